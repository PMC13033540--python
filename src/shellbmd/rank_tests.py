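"""Nonparametric test primitives used throughout the cohort analysis.

Wilcoxon rank-sum (Mann-Whitney) with an exact small-sample mode,
Bonferroni adjustment, the significance-label map used in the group
comparison tables, and Levene's variance-equality test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "wilcoxon_rank_sum",
    "bonferroni_adjust",
    "significance_label",
    "levene_test",
    "DEFAULT_LABEL_MAP",
]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank-sum of the first sample
    (midranks for ties).  The null distribution is enumerated exactly
    when the smaller sample has at most 8 observations and there are no
    ties; otherwise the tie-corrected normal approximation with
    continuity correction is used.  Exact enumeration at these sizes is
    cheap and markedly more accurate than the normal approximation for
    the unbalanced group sizes typical of small cohorts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and min(x.size, y.size) <= 8) else "asymptotic"
    res = _sstats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic + x.size * (x.size + 1) / 2.0)  # U1 -> rank sum of x
    return w, float(min(1.0, res.pvalue))


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``.

    ``m`` defaults to the number of p-values and may exceed it.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, m * p)


#: label thresholds: label applies when ``lower < p_adj <= upper``
DEFAULT_LABEL_MAP = (
    ("****", 0.0, 0.001),
    ("***", 0.001, 0.001),   # unreachable under the default map; kept configurable
    ("**", 0.001, 0.05),
    ("*", 0.05, 0.1),
    ("ns", 0.1, 1.0),
)


def significance_label(adj_p: float, label_map=DEFAULT_LABEL_MAP) -> str:
    """Map an adjusted p-value to its table label.

    Default tiers: ``ns`` for p > 0.1, ``*`` for 0.05 < p <= 0.1,
    ``**`` for 0.001 < p <= 0.05 and ``****`` for p <= 0.001.  Note the
    ``*`` tier labels values above the conventional 0.05 significance
    cut-off; significance *decisions* in this package always use
    p <= 0.05, labels are cosmetic table annotations.
    """
    if not (0 <= adj_p <= 1):
        raise ValueError("adjusted p must lie in [0, 1]")
    for label, lower, upper in label_map:
        if (adj_p > lower or (lower == 0.0 and adj_p == 0.0)) and adj_p <= upper:
            return label
    return "ns"


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances across groups.

    One-way ANOVA on absolute deviations from the per-group center
    (``"mean"`` = classic Levene, ``"median"`` = Brown-Forsythe).
    Degenerate input with zero deviations everywhere returns
    ``(0.0, 1.0)`` by convention.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    centers = [g.mean() if center == "mean" else np.median(g) for g in arrays]
    if all(np.allclose(g, c) for g, c in zip(arrays, centers)):
        return 0.0, 1.0
    stat, p = _sstats.levene(*arrays, center=center)
    return float(stat), float(p)
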