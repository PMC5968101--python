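"""Study-scale head model and the end-to-end irritative-zone pipeline.

``build_study_headmodel`` assembles the desk-scale geometry used for
simulation studies: a three-shell sphere head (rat-sized, 10 mm outer
radius), a 32-electrode upper-hemisphere montage, and a mirrored
left/right cortical source space whose parcels carry Paxinos-Watson-style
identifiers (right 1-48, left 49-96).

``run_pipeline`` chains the analysis stages on a broadband recording:
matched-filter detection, spike / sharp-wave duration banding, per-kind
epoch tensors, constrained PARAFAC, k-means subtype clustering, cluster
means, sLORETA localization, and irritative-zone target/control
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .bsi.localize import IrritativeZoneReport, localize_subtypes, select_target
from .bsi.parcels import Parcellation, default_parcellation
from .errors import ConfigError
from .headmodel.leadfield import LeadField
from .headmodel.montage import Montage, SourceSpace
from .headmodel.reference import apply_average_reference
from .headmodel.sphere import SphereModel, sphere_leadfield
from .iedclass.cluster import (
    ClusterAssignment,
    MeanIED,
    cluster_means,
    cluster_samples,
    merge_similar_clusters,
    merge_small_clusters,
)
from .iedclass.parafac import ParafacResults, parafac, select_rank
from .ieddetect.detect import EventList, detect_ieds, split_by_kind
from .ieddetect.filters import SHARP_WAVE_BAND, SPIKE_BAND, bandpass
from .ieddetect.epochs import IEDTensor, extract_epochs
from .recording import Recording

__all__ = [
    "StudyHeadModel",
    "build_study_headmodel",
    "default_study_config",
    "run_pipeline",
    "PipelineResult",
]

# desk-scale fixture geometry (mm, S/m); conductivities are documented
# configuration, not measured tissue values
STUDY_RADII = (8.5, 9.2, 10.0)
STUDY_CONDUCTIVITIES = (0.33, 0.165, 0.33)
STUDY_PARCEL_IDS = (19, 20, 31, 32, 35, 40, 42, 43, 46, 6, 12, 27)


@dataclass
class StudyHeadModel:
    """Sphere model + montage + mirrored source space + parcellation."""

    sphere: SphereModel
    montage: Montage
    sources: SourceSpace
    parcellation: Parcellation
    leadfield: LeadField  # fixed-orientation (radial), average-referenced

    def sources_in_parcel(self, parcel_id: int) -> np.ndarray:
        return self.parcellation.sources_in(parcel_id)


def _fibonacci_hemisphere(n: int, min_z: float = 0.25) -> np.ndarray:
    """Near-uniform unit directions on the upper spherical cap."""
    i = np.arange(n)
    z = min_z + (1.0 - min_z) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_study_headmodel(
    n_electrodes: int = 32,
    source_subdivisions: int = 3,
    source_radius_mm: float = 7.0,
    parcel_ids: tuple[int, ...] = STUDY_PARCEL_IDS,
    seed: int = 0,
) -> StudyHeadModel:
    """Assemble the simulation-study head model.

    The source space is the dorsal shell of a sphere (rat cortex sits
    dorsally under the mini-cap) and exactly mirror-symmetric:
    right-hemisphere (x > 0) source positions are generated on the shell
    and reflected through the midsagittal plane; right sources are grouped
    into ``parcel_ids`` parcels by k-means on position, and each left
    source inherits the mirrored parcel id + 48.
    """
    from .headmodel.geometry import icosphere

    sphere = SphereModel(
        center=np.zeros(3),
        radii=np.array(STUDY_RADII),
        conductivities=np.array(STUDY_CONDUCTIVITIES),
    )
    elec = _fibonacci_hemisphere(n_electrodes) * STUDY_RADII[-1]
    montage = Montage([f"E{i + 1:02d}" for i in range(n_electrodes)], elec)

    mesh = icosphere(source_subdivisions, source_radius_mm)
    verts = np.asarray(mesh.vertices)
    dorsal = verts[verts[:, 2] > 0.1 * source_radius_mm]
    right = dorsal[dorsal[:, 0] > 0.08 * source_radius_mm]
    km = KMeans(n_clusters=len(parcel_ids), n_init=10, random_state=seed).fit(right)
    right_parcels = np.array([parcel_ids[l] for l in km.labels_])
    left = right * np.array([-1.0, 1.0, 1.0])
    positions = np.vstack([right, left])
    parcels = np.concatenate([right_parcels, right_parcels + 48])
    orientations = positions / np.linalg.norm(positions, axis=1, keepdims=True)

    sources = SourceSpace(
        positions=positions, orientations=orientations, parcel_ids=parcels
    )
    parcellation = default_parcellation(source_parcels=parcels)
    lf = apply_average_reference(sphere_leadfield(sphere, montage, sources))
    return StudyHeadModel(sphere, montage, sources, parcellation, lf)


# canonical simulated cohort: two spike subtypes and one sharp-wave
# subtype in mutually distant parcels whose contralateral partners are
# clear of every generator — the inclusion scenario the target/control
# design assumes (recordings with contaminated controls were excluded
# from the emulated study design)
STUDY_SUBTYPE_PARCELS = (20, 43, 88)  # M2 right, V1B right, S2 left
STUDY_SUBTYPE_DURATIONS_MS = (35.0, 50.0, 130.0)
STUDY_SUBTYPE_KINDS = ("spike", "spike", "sharp_wave")


def default_study_config(
    head: StudyHeadModel,
    sampling_rate: float = 500.0,
    duration_s: float = 60.0,
    n_events: int = 20,
    snr: float = 5.0,
    seed: int = 0,
):
    """The standard simulation-study recording configuration.

    Three IED subtypes (spikes of 35 and 50 ms, one 130 ms sharp-wave)
    from mutually distant parcels, ``n_events`` events each at the given
    SNR.  Each subtype's generator is the source nearest its
    parcel's centroid — the parcel's prototype location — so the subtype
    topographies are stable and representative rather than border cases.
    """
    from .iedsim.recording import SimulationConfig, SubtypeSpec
    from .iedsim.templates import make_ied_template

    subtypes = []
    for parcel, dur, kind in zip(
        STUDY_SUBTYPE_PARCELS, STUDY_SUBTYPE_DURATIONS_MS, STUDY_SUBTYPE_KINDS
    ):
        members = head.parcellation.sources_in(parcel)
        pos = head.sources.positions[members]
        centroid = pos.mean(axis=0)
        src = int(members[np.argmin(np.linalg.norm(pos - centroid, axis=1))])
        tpl = make_ied_template(kind, dur, sampling_rate)
        subtypes.append(
            SubtypeSpec(tpl, src, n_events, moment=1.0, parcel_id=parcel)
        )
    return SimulationConfig(
        n_channels=len(head.montage),
        sampling_rate=sampling_rate,
        duration_s=duration_s,
        subtypes=subtypes,
        snr=snr,
        seed=seed,
    )


@dataclass
class PipelineResult:
    """Everything the analysis chain produced for one recording."""

    events: EventList
    spike_tensor: IEDTensor | None
    sharp_tensor: IEDTensor | None
    spike_model: ParafacResults | None
    sharp_model: ParafacResults | None
    spike_assignment: ClusterAssignment | None
    sharp_assignment: ClusterAssignment | None
    means: list[MeanIED] = field(default_factory=list)
    report: IrritativeZoneReport | None = None

    def combined_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(event peak samples, subtype labels) across both streams;
        sharp-wave cluster labels are offset past the spike clusters."""
        peaks, labels = [], []
        offset = 0
        for tensor, assign in (
            (self.spike_tensor, self.spike_assignment),
            (self.sharp_tensor, self.sharp_assignment),
        ):
            if tensor is None or assign is None or tensor.n_samples == 0:
                continue
            peaks.append(tensor.events.peak_samples)
            labels.append(assign.labels + offset)
            offset += assign.k
        if not peaks:
            return np.array([], dtype=int), np.array([], dtype=int)
        p = np.concatenate(peaks)
        l = np.concatenate(labels)
        order = np.argsort(p)
        return p[order], l[order]


def _classify_stream(
    tensor: IEDTensor,
    rank: int | None,
    k_range: tuple[int, ...],
    seed: int,
    restarts: int,
    max_rank: int,
):
    if tensor.n_samples < 3:
        return None, None
    if rank is None:
        model = select_rank(tensor, max_rank=max_rank, seed=seed, restarts=restarts)
    else:
        model = parafac(tensor, rank, seed=seed, restarts=restarts)
    assignment = cluster_samples(model, k_range=k_range, seed=seed)
    assignment = merge_small_clusters(assignment, assignment.features)
    assignment = merge_similar_clusters(tensor, assignment)
    return model, assignment


def run_pipeline(
    rec: Recording,
    head: StudyHeadModel,
    k_sd: float = 5.0,
    window_ms: float = 300.0,
    rank: int | None = None,
    max_rank: int = 4,
    k_range: tuple[int, ...] = (1, 2, 3, 4),
    lambda_rel: float = 1e-2,
    silence_ratio: float = 0.2,
    seed: int = 0,
    restarts: int = 3,
    epoch_bands: str = "detection",
) -> PipelineResult:
    """Run detection -> classification -> localization on one recording.

    ``epoch_bands`` selects the stream the per-kind epoch tensors are cut
    from: "kind" (spikes from the 15-50 Hz stream, sharp-waves from the
    5-15 Hz stream) or "detection" (both from the broadband detection
    stream).
    """
    if rec.n_channels != head.leadfield.n_electrodes:
        raise ConfigError("recording channel count does not match head model")

    events, det_rec = detect_ieds(rec, k_sd=k_sd)
    spikes, sharps = split_by_kind(events)
    if epoch_bands == "kind":
        stream_rec = {
            "spike": bandpass(rec, *SPIKE_BAND),
            "sharp": bandpass(rec, *SHARP_WAVE_BAND),
        }
    elif epoch_bands == "detection":
        stream_rec = {"spike": det_rec, "sharp": det_rec}
    else:
        raise ConfigError("epoch_bands must be 'kind' or 'detection'")

    result = PipelineResult(
        events=events,
        spike_tensor=None,
        sharp_tensor=None,
        spike_model=None,
        sharp_model=None,
        spike_assignment=None,
        sharp_assignment=None,
    )

    means: list[MeanIED] = []
    for name, stream in (("spike", spikes), ("sharp", sharps)):
        if len(stream) == 0:
            continue
        tensor = extract_epochs(stream_rec[name], stream, window_ms=window_ms)
        model, assignment = _classify_stream(
            tensor, rank, k_range, seed, restarts, max_rank
        )
        if name == "spike":
            result.spike_tensor, result.spike_model = tensor, model
            result.spike_assignment = assignment
        else:
            result.sharp_tensor, result.sharp_model = tensor, model
            result.sharp_assignment = assignment
        if model is not None and assignment is not None:
            means.extend(cluster_means(tensor, assignment))

    result.means = means
    if means:
        locs = localize_subtypes(
            head.leadfield, means, head.parcellation, lambda_rel=lambda_rel
        )
        result.report = select_target(
            locs, head.parcellation, silence_ratio=silence_ratio
        )
    return result
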