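# Methods

`irritmap` implements the analysis chain used to localize the cortical
generators of interictal epileptiform discharges (IEDs) — the *irritative
zones* — from multichannel scalp EEG in small animals, and to carry the
localization through to paired target-vs-control histology statistics.
This note documents the models, the defaults and why they were chosen,
what the synthetic data do and do not emulate, and the numerical choices
that matter.

## Forward head models

**Analytic multi-shell sphere.** Nested concentric shells (radii
strictly increasing, per-shell conductivities, non-conducting exterior).
The dipole potential is expanded in Legendre harmonics; per degree *n*
the radial profile in each shell is `A r^n + B r^-(n+1)`, coefficients are
propagated across interfaces by continuity of potential and radial
current density, and the outer boundary carries zero normal current.
Radii are normalized by the outer radius for conditioning. The series is
truncated at `series_terms` (default 200) with an early stop when three
consecutive terms contribute less than `tol = 1e-12` of the running
value; 200 terms are needed for ~1e-6 relative accuracy at source
eccentricities near 0.9 of the innermost shell. With equal shell
conductivities the model reduces to the classical homogeneous-sphere
solution, whose closed form (obtained by summing the series through the
generating functions of `P_n` and `P_n'`) serves as the independent
oracle in the tests.

**Surface BEM.** Double-layer collocation on nested closed triangulated
surfaces: one potential value per vertex, the signed solid angle of each
triangle (van Oosterom–Strackee) distributed equally to its three
vertices. A triangle subtends zero solid angle from a point in its own
plane, so triangles incident to the collocation vertex drop out exactly
and no ad hoc auto-element correction is needed; the nesting of surfaces
is verified through the same solid-angle closure (4π for an enclosing
surface, 0 for an enclosed one). The exterior Neumann problem's rank-1
null space (a global offset) is removed by Lynn–Timlake deflation before
a dense LU solve. Electrodes snap to the nearest scalp vertex (error if
farther than 2 mm). No isolated-skull approach is used; the fixture
conductivity contrast (0.33 / 0.165 / 0.33 S/m) is mild, and the sphere
oracle bounds the error (RDM ≤ 0.006, magnitude ratio ≈ 0.95 at 2562
vertices per surface). Fixture conductivities are configuration, not
measured tissue values.

Units are fixed package-wide: mm, S/m, nA·m, µV.

## Synthetic recordings

The generator emulates 32-channel rat scalp EEG containing 2–5 IED
subtypes: each subtype is a cortical dipole (a lead-field column) driven
by a unit-peak bi-Gaussian waveform (fast rise, slower decay, default
decay/rise ratio 2) parameterized exactly by its full width at half
maximum — 20–70 ms for spikes, 70–200 ms for sharp-waves.

Events are scheduled on an interleaved slot lattice (slot length =
minimum gap, default 500 ms, ±100 ms jitter): each subtype draws slots
from its own congruence class with its own seeded stream, which
guarantees the minimum inter-event gap *and* makes event insertion
additive across subtypes (simulating subtypes separately and summing
reproduces the joint clean signal bit-for-bit).

Background noise is a per-channel mixture of white Gaussian and a
unit-variance AR(1) process: `pink_fraction = 0.5`, `ar_coeff = 0.9`
(≈8 Hz knee at 500 Hz sampling). This is a generic 1/f-like sedated-
rodent background. The colored share and knee were chosen so that the
background is low-frequency dominated yet does not coincide spectrally
with the slowest IEDs — a background whose power sits entirely inside
the sharp-wave band would make the stated operating point (95%
sensitivity at SNR 5) unattainable for *any* detector, including a
whitened matched filter. Subtype scalp topographies are scaled to a
common best-channel peak (100 µV) and the noise is scaled post hoc so
that the peak-to-background-sd ratio on the best channel equals the
configured SNR for every subtype.

The canonical simulation cohort (used by the end-to-end tests and the
acceptance script) has three subtypes — spikes of 35 and 50 ms and a
130 ms sharp-wave, 20 events each at SNR 5 in 60 s at 500 Hz — placed at
the prototype (centroid-nearest) sources of three mutually distant
parcels whose contralateral partners are clear of every generator. That
arrangement mirrors the emulated study's inclusion criterion (recordings
without a clean contralateral control were excluded) and the visibly
separable subtype clusters of the original classification.

What the generator does **not** emulate: artifacts (EMG, eye, motion),
non-stationary background, propagating or multifocal single events,
seizures, and realistic skull/scalp geometry. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
clinical-grade performance on real recordings.

Histology tables: for each of N = 8 paired target/control zones and each
biomarker, six replicate "image" measurements are drawn around a
zone-level value with `target = control × (1 + effect)`. Default
effects follow the qualitative pattern of irritative-zone histology
(neuronal loss; denser processes; elevated GFAP, IL-1β, TNF-α, HMGB1,
NR2B, mGluR5 and perivascular cuffing; a small non-significant GABA-A α6
increase; essentially unchanged cortical thickness, baseline 1.73 mm).
Noise magnitudes put the significant markers near a paired standardized
effect of d ≈ 1.5 at N = 8; count-type markers are rounded to
non-negative integers.

## Detection

Detection runs on a 1–45 Hz zero-phase band of the raw recording.
Unipolar 20–200 ms IED humps keep most of their energy below 15 Hz, so
thresholding inside the narrow 15–50 Hz (spike) or 5–15 Hz (sharp-wave)
analysis bands discards most of the available SNR; those bands belong to
the later waveform-separation stage, not to detection.

The default statistic is a whitened multi-scale matched filter: each
channel's robust z-score (median/MAD) is whitened by a per-channel AR(1)
fit of the background, correlated with whitened bi-Gaussian templates on
a duration grid (30/50/90/150 ms), renormalized robustly, and pooled by
the across-channel maximum. The threshold is `median + k·(robust sd)` of
the pooled statistic, k = 5 by default; candidates from all scales are
merged within a 200 ms refractory window (largest statistic wins), and
peak times are refined on the unsmoothed signal within ±10 ms (exact to
±1 sample on noiseless data). A classical per-channel `median + k·MAD`
rule remains available (`statistic="per_channel"`). Raising k can only
remove detections (monotonicity).

Event duration is estimated on a topography-weighted virtual channel
(the deviation pattern at the peak, restricted to channels deflected
beyond 2.5 robust sds, projected onto the data): the local-baseline-
corrected segment is scored against unit-norm bi-Gaussian templates over
a geometric 18–220 ms FWHM grid and the best-scoring width is reported.
Template matching integrates over the whole waveform and is far more
robust to colored noise than walking half-maximum crossings. Durations
outside [20, 200] ms are discarded; [20, 70) ms is a spike, [70, 200] ms
a sharp-wave (70 ms counts as sharp-wave).

## Subtype classification

Detected events become an electrodes × time × samples tensor (300 ms
peak-centered epochs, baseline = mean of the first 20% of the window),
built per kind. The tensor is decomposed by constrained PARAFAC
(alternating least squares): per-mode constraints are `none` (ridge-
stabilized least squares), `nonneg` (row-wise NNLS through the normal
equations), or `ortho` (orthogonal Procrustes). Defaults: orthogonal
temporal atoms, non-negative sample signatures. Every block update
minimizes the objective over its block, so the fit (explained variance)
is non-decreasing within a run — asserted on every fit; the best of
several seeded restarts (default 10; the first restart uses an SVD-based
initialization) is kept, with `tol = 1e-8` relative fit change and at
most 500 iterations.

Rank selection uses the core-consistency diagnostic (CORCONDIA): the
least-squares Tucker core of the fitted factors compared with the CP
superdiagonal, 100 by definition at one component. Because a single
component always scores 100, "smallest adequate rank" is degenerate; the
package grows the rank and keeps the **largest** rank whose score stays
at or above the threshold (default 80, cap 8).

Sample signatures are clustered by k-means. The cluster count is chosen
by the gap statistic (uniform bounding-box references, one-standard-
error rule), which genuinely supports k = 1 — a single unimodal subtype
must not be split, and the raw silhouette cannot express that; the
silhouette rule remains available. Two pipeline-level cleanups follow:
clusters below 10% of the stream are absorbed into the nearest centroid
(a real subtype fires many times per recording), and clusters whose
peak-window topography × GFP-profile correlation exceeds 0.9 are merged
(amplitude variability can split one generator into two clusters with
identical spatio-temporal patterns). Cluster means ("mean value X") are
the per-subtype representative IEDs.

## Source localization and target selection

Cluster-mean topographies are analyzed at 2/3 of the IED peak on the
rising phase of the global field power (GFP) curve, linearly
interpolated and snapped to the nearest sample (a falling-phase option
exists). The inverse is sLORETA: the minimum-norm estimate
`T = Gᵀ(GGᵀ + λH)⁺` with `H` the average-reference operator and
`λ = lambda_rel · trace(GGᵀ)/n`, standardized by the diagonal (blocks)
of the resolution kernel `S = TG`. For a noiseless single-source
topography the standardized power peaks exactly at the true source;
this zero-localization-error property is verified exhaustively on the
study source space. `lambda_rel` defaults: 1e-4 (noiseless analyses) to
1e-2 (SNR-5 cluster means); results in the study regime are insensitive
across that range.

Parcel power is the **maximum** over member sources (the mean dilutes
focal peaks in large parcels and misassigned ~30% of noiseless maps on
the study geometry; the max preserves parcel-level exactness). The
irritative-zone target is the peak parcel of the most frequent subtype
(ties broken by peak power); the control is its contralateral partner
(left id = right id + 48 in the 96-id Paxinos–Watson-style convention).
The contralateral-silence verdict requires the control parcel's power in
*every* subtype's map to stay below `silence_ratio` (default 0.2) times
that subtype's own peak activation — subtypes that generate elsewhere
are judged against their own maxima, since their power at the target
parcel is itself noise.

Sectioning coordinates: fixation shrinkage is corrected by
`alpha = L / (a − p)` with `L` the measured specimen length and `a`, `p`
the Bregma-referenced atlas anterior/posterior extents (anterior
positive, `a = 5.6 mm` by convention; `p` is configuration). Bregma-
referenced atlas offsets map onto the specimen by multiplication with
alpha; the anterior-cortex-to-Bregma distance B2 and the Bregma-to-block
distance l follow directly.

## Histology statistics

Stained-area fraction: morphological-opening background subtraction
(disk radius 15 px), binarization at an intensity quantile (default
0.95 — the "frequency threshold" of interactive image software read as
keeping the brightest 5% of pixels), 8-connected components, objects
below 5 px removed. Object counts are the retained component count.
Synthetic disk-blob images (labelled synthetic; they do not emulate real
immunofluorescence texture) exercise the contracts.

Replicates are averaged to one value per zone per region; the unit of
analysis is the zone (N = 8). Per marker, Shapiro–Wilk on the paired
differences at α = 0.05 gates a paired t-test (normal) versus the
Wilcoxon signed-rank test. The Wilcoxon p is exact for up to 25
informative pairs — the null distribution of the signed-rank sum
(mid-ranks doubled to an integer grid) is built by dynamic programming,
equivalent to full 2ⁿ enumeration — and a tie- and continuity-corrected
normal approximation beyond. Two-sided p-values are tail probabilities
of |W − μ| under the symmetric null. Stars: * p<0.05, ** p<0.01,
*** p<0.001. No multiple-testing correction is applied by default
(each marker is reported marginally); a Holm adjustment is available.

## Problem sizes and determinism

Default analyses are sized for a single CPU: 60 s recordings at 500 Hz,
274-source study space, 2562-vertex BEM validation meshes, 20-seed
end-to-end replications, 2000-replicate statistical calibrations. All
randomness flows through explicit integer seeds (`numpy` Generator
streams); recordings and tables are bit-reproducible under a fixed seed.

## Known limitations

- Spherical geometry only; no realistic rat head, no anisotropy, no FEM.
- The BEM is vertex-collocation without the isolated-skull transform and
  degrades for strong conductivity contrasts (e.g. 1:80 skull ratios).
- Detection templates and the simulator share the bi-Gaussian family;
  real IED morphology (polyphasic spikes, spike-and-wave complexes) will
  lower matched-filter efficiency.
- The silence verdict and target selection assume one dominant generator
  per subtype; propagating sources violate that premise.
- Perivascular-cuff *detection* on images is out of scope; only the
  count/area contracts on synthetic blobs and the downstream paired
  statistics are implemented.
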