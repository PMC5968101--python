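# irritmap

Irritative-zone mapping for preclinical EEG source imaging: detect
interictal epileptiform discharges (IEDs) in multichannel rat scalp EEG,
classify them into subtypes, localize each subtype's cortical generator,
and run the paired target-vs-control histology statistics that
characterize the localized tissue.

## Who this is for

Groups doing brain source imaging (BSI) in rodent epilepsy models: you
record scalp EEG with a high-density mini-cap, you want the *irritative
zones* — the cortical patches generating spikes (20–70 ms) and
sharp-waves (70–200 ms) between seizures — and you then section the
brain at those coordinates and compare histological biomarkers against
the contralateral healthy control region.

## The analysis chain

1. **Forward model** — analytic multi-shell sphere and a double-layer
   collocation BEM on nested surfaces give the lead field `G`
   (µV per nA·m) from cortical dipoles to scalp electrodes.
2. **Detection** — a whitened multi-scale matched filter on robust
   per-channel z-scores; event duration (FWHM by template matching)
   assigns the spike / sharp-wave kind.
3. **Classification** — the epochs form a tensor `V ∈ R^{e×t×s}`
   (electrodes × time × samples) decomposed by constrained PARAFAC,

   `V ≈ Σ_f  f^e_f ⊗ f^t_f ⊗ f^s_f`,

   with orthogonal temporal atoms and non-negative sample signatures;
   k-means on the sample signatures separates the IED subtypes, and
   per-cluster mean IEDs are the subtype representatives.
4. **Localization** — each subtype's scalp topography at 2/3 of its peak
   (rising phase of the global field power) is inverted with sLORETA,
   the standardized minimum-norm estimate
   `ĵ = Gᵀ(GGᵀ + λH)⁺ v`, power `ĵᵢᵀ S_ii⁻¹ ĵᵢ` with `S = Gᵀ(GGᵀ+λH)⁺G`;
   the target is the peak parcel of the most frequent subtype, the
   control its contralateral partner (Paxinos–Watson-style ids, right
   1–48 / left 49–96), and the report records whether the control is
   silent in every subtype's map.
5. **Sectioning** — the fixation-shrinkage factor `α = L/(a − p)` maps
   Bregma-referenced atlas coordinates onto the shrunken specimen.
6. **Histology statistics** — stained-area fractions and object counts
   on images, replicates averaged per zone, and a normality-gated paired
   test per biomarker (paired t or exact Wilcoxon signed-rank) with the
   usual star convention.

A synthetic-data module generates recordings with known subtypes,
sources and timings, plus paired histology tables with configurable
effects, so the whole chain is testable without any recorded data.

## Worked example

```python
from irritmap import build_study_headmodel, default_study_config, run_pipeline
from irritmap.iedsim import simulate_recording

head = build_study_headmodel()                 # sphere head, 32 electrodes,
cfg = default_study_config(head, seed=3)       # 3 subtypes x 20 events, SNR 5
rec, truth = simulate_recording(cfg, head.leadfield)

result = run_pipeline(rec, head, seed=3)
rep = result.report
print(f"events detected : {len(result.events)}")
print(f"subtypes        : {rep.n_spike_subtypes} spike, "
      f"{rep.n_sharp_wave_subtypes} sharp-wave")
print(f"target parcel   : {rep.target_parcel} ({'/'.join(rep.target_label)})")
print(f"control parcel  : {rep.control_parcel} ({'/'.join(rep.control_label)})")
print(f"contralateral silence: {rep.silence_verdict}")
```

prints

```
events detected : 61
subtypes        : 2 spike, 1 sharp-wave
target parcel   : 20 (M2/right)
control parcel  : 68 (M2/left)
contralateral silence: True
```

The simulated recording contained two spike subtypes (M2 right, V1B
right) and one sharp-wave subtype (S2 left), 20 events each; the
pipeline recovered all three subtypes (61 detections include one false
alarm), selected the most frequent subtype's generator M2-right as the
target, paired it with its contralateral homologue M2-left as control,
and confirmed the control is silent in every subtype's source map — the
precondition for using it as the healthy reference in the histology
comparison.

The same stages are available from the shell:

```sh
irritmap simulate --seed 3 --out sim/
irritmap detect   --eeg sim/recording.txt --out events.csv
irritmap localize --eeg sim/recording.txt --seed 3 --out report.json
irritmap report   --table sim/histology.csv --out stats.csv
```

## Layout

```
src/irritmap/
  headmodel/   sphere + BEM lead fields, montage, average reference
  iedsim/      synthetic recordings and histology tables
  ieddetect/   filtering, matched-filter detection, epoch tensors
  iedclass/    constrained PARAFAC, CORCONDIA, clustering
  bsi/         sLORETA, parcellation, target/control, sectioning
  histostats/  image quantification and paired statistics
  pipeline.py  study head model + end-to-end driver
  cli.py       irritmap {simulate,detect,classify,localize,report}
docs/methods.md   model and parameter documentation
```
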