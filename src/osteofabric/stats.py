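"""Group statistics for the study design: rank tests, Dunn's follow-up,
Pearson correlation, and the radiographic percent-increase measure.

All tests are two-sided. Rank tests switch between exact enumeration (small
samples, no ties) and the tie-corrected, continuity-corrected normal
approximation; the branch taken is recorded in the result so p-values are
bit-reproducible and auditable. The exact/approximate switch points are
fixed constants (Mann-Whitney: min(n_x, n_y) <= 8; Wilcoxon: n <= 15).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "dunn_multiple_comparison",
    "pearson_correlation",
    "percent_increase",
]

MANN_WHITNEY_EXACT_MAX = 8
WILCOXON_EXACT_MAX = 15

METHOD_EXACT = "exact"
METHOD_NORMAL = "normal-approximation"


@dataclass
class GroupComparison:
    statistic: float
    p_two_sided: float
    method: str
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_two_sided}")


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U rank-sum test.

    (Often reported as a "Mann-Whitney t-test"; it is the U test.) Exact
    p by enumeration when min(n_x, n_y) <= 8 and there are no cross-sample
    ties; otherwise the tie-corrected normal approximation with continuity
    correction. The statistic is U for the first sample with midrank ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (min(x.size, y.size) <= MANN_WHITNEY_EXACT_MAX) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return GroupComparison(
        statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method=METHOD_EXACT if exact else METHOD_NORMAL,
        n_x=int(x.size),
        n_y=int(y.size),
    )


def wilcoxon_signed_rank(paired_diffs) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. W is the smaller of the signed-rank sums.
    Exact p for n <= 15 without tied magnitudes, normal approximation with
    continuity correction otherwise.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    has_ties = np.unique(np.abs(d)).size < d.size
    exact = d.size <= WILCOXON_EXACT_MAX and not has_ties
    res = sps.wilcoxon(
        d,
        alternative="two-sided",
        zero_method="wilcox",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    return GroupComparison(
        statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method=METHOD_EXACT if exact else METHOD_NORMAL,
        n_x=int(d.size),
        n_y=int(d.size),
    )


def dunn_multiple_comparison(groups: list) -> np.ndarray:
    """Dunn's rank-based pairwise comparisons after a global rank test.

    Pooled midranks; z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) *
    (1/n_i + 1/n_j)) with tie correction T = sum(t^3 - t)/(12(N-1));
    two-sided p adjusted by the Bonferroni factor k(k-1)/2 (the classical
    Dunn family-wise adjustment), capped at 1. Returns a symmetric k x k
    matrix of adjusted p-values (diagonal 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(groups)
    n_comparisons = k * (k - 1) // 2
    p = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            p_raw = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p[i, j] = p[j, i] = min(1.0, p_raw * n_comparisons)
    return p


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment r and its two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def percent_increase(tumor_area: float, control_area: float) -> float:
    """Percent increase of the injected side over the paired contralateral.

    100 * (tumor_area - control_area) / control_area, areas in mm^2.
    """
    if control_area <= 0:
        raise ValueError("control_area must be > 0")
    return 100.0 * (tumor_area - control_area) / control_area
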