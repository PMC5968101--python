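"""Subtype localization and irritative-zone target/control selection.

Each IED subtype's cluster-mean topography, taken at its 2/3-peak rising
latency, is inverted with sLORETA; the subtype's generator is the parcel
with the highest mean standardized power.  The irritative-zone target is
the peak parcel of the most frequent subtype (ties broken by peak power),
its control is the contralateral homologue, and the contralateral-silence
criterion requires every subtype's control-parcel power to stay below a
fraction of its target-parcel power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import ContractError, SelectionError
from ..headmodel.leadfield import LeadField
from ..iedclass.cluster import MeanIED
from .latency import twothirds_latency
from .parcels import Parcellation
from .sloreta import SourceMap, sloreta

__all__ = ["IrritativeZoneReport", "localize_subtypes", "select_target"]


@dataclass
class SubtypeLocalization:
    source_map: SourceMap
    peak_parcel: int
    peak_power: float
    latency_ms: float
    kind: str
    n_events: int


@dataclass
class IrritativeZoneReport:
    """Target/control selection outcome (per-recording summary).

    Mirrors the per-rat reporting scheme: spike and sharp-wave subtype
    counts, every localized structure, the most frequent subtype's peak
    parcel as target, and its contralateral partner as control.
    """

    subtypes: list[SubtypeLocalization]
    target_parcel: int
    control_parcel: int
    target_label: tuple[str, str]
    control_label: tuple[str, str]
    silence_verdict: bool
    silence_ratio: float
    control_target_ratios: list[float]
    n_spike_subtypes: int
    n_sharp_wave_subtypes: int
    localized_parcels: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "S_subtypes": self.n_spike_subtypes,
            "SW_subtypes": self.n_sharp_wave_subtypes,
            "localized_structures": self.localized_parcels,
            "target_parcel": self.target_parcel,
            "target_label": list(self.target_label),
            "control_parcel": self.control_parcel,
            "control_label": list(self.control_label),
            "contralateral_silence": self.silence_verdict,
            "silence_ratio": self.silence_ratio,
            "control_target_ratios": self.control_target_ratios,
            "subtype_counts": [s.n_events for s in self.subtypes],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def localize_subtypes(
    lf: LeadField,
    means: list[MeanIED],
    parcellation: Parcellation,
    lambda_rel: float = 1e-2,
) -> list[SubtypeLocalization]:
    """One sLORETA map per subtype at its 2/3-peak latency.

    Parcel power is the mean standardized power over the parcel's member
    sources; the subtype's peak parcel maximizes it.
    """
    out = []
    if parcellation.source_parcels.size != lf.n_sources:
        raise ContractError("parcellation does not cover the source space")
    for i, mean in enumerate(means):
        if mean.time_course.shape[0] != lf.n_electrodes:
            raise ContractError("channel count mismatch between mean IED and lead field")
        latency = twothirds_latency(mean)
        topo = mean.topography_at(latency)
        topo = topo - topo.mean()
        smap = sloreta(lf, topo, lambda_rel=lambda_rel,
                       latency_ms=latency, subtype=i)
        powers = smap.parcel_powers(parcellation.source_parcels)
        peak_parcel = max(powers, key=powers.get)
        out.append(
            SubtypeLocalization(
                source_map=smap,
                peak_parcel=peak_parcel,
                peak_power=powers[peak_parcel],
                latency_ms=latency,
                kind=mean.kind,
                n_events=mean.n_events,
            )
        )
    return out


def select_target(
    localizations: list[SubtypeLocalization],
    parcellation: Parcellation,
    silence_ratio: float = 0.2,
) -> IrritativeZoneReport:
    """Pick the irritative-zone target and check contralateral silence.

    Target: peak parcel of the most frequent subtype (ties resolved by the
    larger peak power).  Control: the target's contralateral parcel.
    Verdict: true only if the control parcel is silent in every subtype's
    map — its power at most ``silence_ratio`` times that subtype's own
    peak activation.  (Subtypes other than the most frequent one peak in
    other parcels, so their maps are judged against their own maxima.)
    """
    if not localizations:
        raise SelectionError("no subtypes to select a target from")
    best = max(localizations, key=lambda s: (s.n_events, s.peak_power))
    target = best.peak_parcel
    try:
        control = parcellation.contralateral(target)
    except Exception as exc:
        raise SelectionError(f"target parcel {target} has no contralateral partner") from exc
    if control not in parcellation.table:
        raise SelectionError(f"control parcel {control} missing from parcellation")

    ratios = []
    silent = True
    for s in localizations:
        powers = s.source_map.parcel_powers(parcellation.source_parcels)
        p_own_peak = powers.get(s.peak_parcel, 0.0)
        p_control = powers.get(control, 0.0)
        ratio = p_control / p_own_peak if p_own_peak > 0 else np.inf
        ratios.append(float(ratio))
        if ratio > silence_ratio:
            silent = False

    kinds = [s.kind for s in localizations]
    return IrritativeZoneReport(
        subtypes=localizations,
        target_parcel=target,
        control_parcel=control,
        target_label=parcellation.label(target),
        control_label=parcellation.label(control),
        silence_verdict=silent,
        silence_ratio=silence_ratio,
        control_target_ratios=ratios,
        n_spike_subtypes=sum(k == "spike" for k in kinds),
        n_sharp_wave_subtypes=sum(k == "sharp_wave" for k in kinds),
        localized_parcels=sorted({s.peak_parcel for s in localizations}),
    )
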