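"""Paired target-vs-control tests with a normality gate.

The testing scheme follows common histology practice: Shapiro-Wilk decides
whether the paired differences look Gaussian; if so a paired t-test is
used, otherwise the Wilcoxon signed-rank test.  The Wilcoxon p-value is
exact — the null distribution of the signed-rank sum (mid-ranks for ties)
is built by dynamic programming over all 2^n equiprobable sign assignments
— for up to 25 informative pairs, beyond which a tie-corrected normal
approximation with continuity correction is used.  Two-sided p-values are
tail probabilities of |W - mu| under the symmetric null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from ..errors import ConfigError

__all__ = ["TestResult", "paired_compare", "wilcoxon_signed_rank", "stars"]

_EXACT_LIMIT = 25


def stars(p_value: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass
class TestResult:
    marker: str
    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    direction: str  # "increase" | "decrease" | "none"
    n_pairs: int
    significance: str
    degenerate: bool = False


def _signed_ranks(differences: np.ndarray) -> np.ndarray:
    """Mid-ranks of |d| for the non-zero differences."""
    return scipy.stats.rankdata(np.abs(differences))


def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank statistic and two-sided p.

    Zero differences are dropped; the statistic reported is the smaller of
    the positive- and negative-rank sums.  Exact (full null distribution,
    ties mid-ranked) for n <= 25 informative pairs, normal approximation
    with continuity and tie correction above.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 3:
        raise ConfigError("need at least 3 non-zero differences")
    ranks = _signed_ranks(d)
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    statistic = min(w_pos, w_neg)
    mu = n * (n + 1) / 4.0

    if n <= _EXACT_LIMIT:
        # DP over the doubled (integer) rank grid: distribution of W+
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        counts /= counts.sum()
        support = np.arange(total + 1) / 2.0
        dev = np.abs(support - mu)
        observed_dev = abs(w_pos - mu)
        p = float(counts[dev >= observed_dev - 1e-9].sum())
        return statistic, min(p, 1.0)

    # normal approximation with tie correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    dev = abs(w_pos - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(z)
    return statistic, min(p, 1.0)


def paired_compare(
    target: np.ndarray,
    control: np.ndarray,
    alpha_normality: float = 0.05,
    marker: str = "",
) -> TestResult:
    """Normality-gated paired comparison of target vs control zone values.

    Shapiro-Wilk on the paired differences at ``alpha_normality`` selects a
    paired t-test (normal) or the Wilcoxon signed-rank test (non-normal);
    p-values are two-sided.  All-zero differences yield a degenerate result
    with p = 1.
    """
    t = np.asarray(target, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ConfigError("target and control must be equal-length vectors")
    n = t.size
    if n < 3:
        raise ConfigError("need at least 3 zone pairs")
    d = t - c
    mean_d = float(d.mean())
    direction = "increase" if mean_d > 0 else ("decrease" if mean_d < 0 else "none")

    if np.all(d == 0):
        return TestResult(marker, "degenerate", 0.0, 1.0, "none", n, "", True)

    if np.ptp(d) == 0:
        normal = True  # constant non-zero differences: Shapiro undefined
    else:
        normal = scipy.stats.shapiro(d).pvalue >= alpha_normality

    if normal:
        res = scipy.stats.ttest_rel(t, c)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "paired_t"
    else:
        stat, p = wilcoxon_signed_rank(d)
        test = "wilcoxon"
    return TestResult(marker, test, stat, p, direction, n, stars(p))
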