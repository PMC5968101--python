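"""Paired target/control histology measurement tables with known effects.

The generator emulates the quantification scheme used for irritative-zone
histology: for each of ``n_zones`` paired target (T) / control (C) cortical
regions and each biomarker, six replicate image measurements are drawn around
a zone-level value.  The target zone mean is ``control * (1 + effect)``, so a
zero effect gives an exact paired null.

Default marker effects reflect the qualitative pattern reported for focal
cortical dysplasia irritative zones: neuronal loss (fewer Nissl somas),
denser neuronal processes, glioreactivity (GFAP), elevated inflammatory
(IL-1beta, TNF-alpha, HMGB1) and glutamatergic (NR2B, mGluR5) markers,
increased perivascular cuffing, an inconclusive GABA-A alpha-6 change, and
essentially unchanged cortical thickness.  Effect and noise magnitudes are
sized so that, at N = 8 zones, the significant markers carry a paired
standardized effect of about d = 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError

__all__ = ["MarkerSpec", "default_markers", "simulate_histology_tables"]


@dataclass
class MarkerSpec:
    """One biomarker's generative parameters.

    ``effect`` is the relative target-vs-control change; ``kind`` is
    "count" (values rounded to non-negative integers), "area" (stained-area
    fraction in arbitrary units) or "length" (mm).
    """

    name: str
    baseline: float
    effect: float
    kind: str = "area"
    zone_sd: float = 0.15     # between-zone spread, relative to baseline
    noise_sd: float = 0.29    # paired zone-level noise, relative to baseline
    replicate_sd: float = 0.29  # within-zone replicate noise, rel. to baseline


def default_markers() -> list[MarkerSpec]:
    """Study-condition marker panel with its configured effect sizes."""
    return [
        MarkerSpec("soma_count", 80.0, -0.35, kind="count"),
        MarkerSpec("process_count", 120.0, +0.50, kind="count"),
        MarkerSpec("GFAP_area", 1.0, +0.50),
        MarkerSpec("IL1b_area", 1.0, +0.50),
        MarkerSpec("TNFa_area", 1.0, +0.60),
        MarkerSpec("HMGB1_area", 1.0, +0.45),
        MarkerSpec("NR2B_area", 1.0, +0.45),
        MarkerSpec("mGluR5_area", 1.0, +0.60),
        MarkerSpec("GABAAa6_area", 1.0, +0.10),
        MarkerSpec("cuffing_density", 10.0, +0.50, kind="count"),
        MarkerSpec("cortical_thickness_mm", 1.73, -0.052, kind="length",
                   zone_sd=0.20, noise_sd=0.15, replicate_sd=0.05),
    ]


def simulate_histology_tables(
    n_zones: int = 8,
    markers: list[MarkerSpec] | None = None,
    effect_sizes: dict[str, float] | float | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    n_replicates: int = 6,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate a paired measurement table.

    Parameters
    ----------
    n_zones : number of paired irritative/control zones (>= 2).
    markers : marker panel; defaults to :func:`default_markers`.
    effect_sizes : overrides — a scalar applied to every marker or a
        ``{marker_name: effect}`` mapping.
    noise_sd : override of the relative paired and replicate noise for every
        marker (0 gives exactly zero paired differences at zero effect).
    seed : RNG seed.
    n_replicates : images measured per zone per region (six at 20X in the
        emulated protocol).

    Returns
    -------
    table : tidy DataFrame with columns
        ``zone, marker, region ("target"|"control"), replicate, value``.
    truth : mapping marker name -> configured relative effect.
    """
    if n_zones < 2:
        raise ConfigError("n_zones must be >= 2")
    if noise_sd is not None and noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    markers = [MarkerSpec(**vars(m)) for m in (markers or default_markers())]
    if effect_sizes is not None:
        if np.isscalar(effect_sizes):
            for m in markers:
                m.effect = float(effect_sizes)
        else:
            for m in markers:
                if m.name in effect_sizes:
                    m.effect = float(effect_sizes[m.name])
    if noise_sd is not None:
        for m in markers:
            m.noise_sd = noise_sd
            m.replicate_sd = noise_sd

    rng = np.random.default_rng(seed)
    rows = []
    for m in markers:
        zone_vals = m.baseline * (1.0 + m.zone_sd * rng.standard_normal(n_zones))
        zone_vals = np.maximum(zone_vals, 0.05 * m.baseline)
        paired_noise = m.baseline * m.noise_sd * rng.standard_normal(n_zones)
        target_vals = zone_vals * (1.0 + m.effect) + paired_noise
        for z in range(n_zones):
            for region, center in (("target", target_vals[z]), ("control", zone_vals[z])):
                reps = center + m.baseline * m.replicate_sd * rng.standard_normal(
                    n_replicates
                )
                if m.kind == "count":
                    reps = np.maximum(np.round(reps), 0.0)
                else:
                    reps = np.maximum(reps, 0.0)
                for r, v in enumerate(reps):
                    rows.append((z, m.name, region, r, float(v)))
    table = pd.DataFrame(
        rows, columns=["zone", "marker", "region", "replicate", "value"]
    )
    truth = {m.name: m.effect for m in markers}
    return table, truth
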