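"""Per-marker summary of a paired measurement table.

The unit of analysis is the zone: replicate images are averaged to one
value per zone per region before pairing, and each marker is tested
independently (no multiplicity correction by default, with an optional
Holm adjustment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .inference import paired_compare, stars

__all__ = ["zone_means", "summarize"]

_REQUIRED = {"zone", "marker", "region", "value"}


def zone_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicates: one row per (zone, marker, region)."""
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ConfigError(f"measurement table lacks columns {sorted(missing)}")
    bad = set(table["region"].unique()) - {"target", "control"}
    if bad:
        raise ConfigError(f"unknown regions {sorted(bad)}")
    return (
        table.groupby(["zone", "marker", "region"], as_index=False)["value"].mean()
    )


def summarize(
    table: pd.DataFrame,
    alpha_normality: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Mean +/- SD per region, paired test, and significance per marker.

    Returns one row per marker with target/control means and SDs, the test
    chosen by the normality gate, the two-sided p-value, direction of
    change, N (zone pairs), and significance stars.
    """
    zm = zone_means(table)
    rows = []
    for marker, sub in zm.groupby("marker", sort=False):
        wide = sub.pivot(index="zone", columns="region", values="value")
        if wide.isna().any().any():
            raise ConfigError(f"marker {marker}: unpaired zones present")
        t = wide["target"].to_numpy()
        c = wide["control"].to_numpy()
        res = paired_compare(t, c, alpha_normality=alpha_normality, marker=marker)
        rows.append(
            {
                "marker": marker,
                "n_pairs": res.n_pairs,
                "target_mean": t.mean(),
                "target_sd": t.std(ddof=1),
                "control_mean": c.mean(),
                "control_sd": c.std(ddof=1),
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "direction": res.direction,
                "significance": res.significance,
            }
        )
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
        out["significance"] = [stars(p) for p in adj]
    return out
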