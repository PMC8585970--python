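"""Nonparametric group comparisons.

Mann–Whitney U for two groups, Kruskal–Wallis (ANOVA on ranks) for three or
more, Dunn's z pairwise comparisons with Bonferroni adjustment afterwards,
and the usual star labelling of p-values.  Mann–Whitney p-values are exact
(full permutation distribution) for small tie-free samples and use the
tie-corrected, continuity-corrected normal approximation otherwise; the
method actually used is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._exceptions import EmptyGroupError, ParameterError

#: samples with combined size up to this and no ties get an exact p-value
EXACT_MW_CUTOFF = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[int] = None
    pair: Optional[tuple[str, str]] = None
    adjusted_p: Optional[float] = None


def mann_whitney_u(a, b) -> TestResult:
    """Two-tailed Mann–Whitney U test.

    The statistic is U for the first sample (mid-ranks for ties).  The
    p-value is exact by full enumeration when n_a + n_b <= 12 and the data
    are tie-free, otherwise a normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroupError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size + b.size <= EXACT_MW_CUTOFF:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal-approximation"
    return TestResult(
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), method=method
    )


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected, chi-square approximation)."""
    if len(groups) < 2:
        raise ParameterError("kruskal_wallis requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise EmptyGroupError("all groups must be non-empty")
    H, p = stats.kruskal(*arrays)
    return TestResult(
        statistic=float(H),
        p_value=float(p),
        method="chi-square-approximation",
        df=len(groups) - 1,
    )


def dunns_method(
    groups: Sequence, labels: Optional[Sequence[str]] = None
) -> list[TestResult]:
    """Dunn's rank-based pairwise comparisons after Kruskal–Wallis.

    For groups i, j with mean pooled ranks R̄_i, R̄_j,

        z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) · (1/n_i + 1/n_j))

    with tie term T = Σ(t³−t) / (12(N−1)).  Two-sided normal p-values are
    Bonferroni-adjusted over all pairs.  When every pooled value is tied
    the variance term vanishes; the comparison is then defined as z = 0,
    p = 1.
    """
    if len(groups) < 2:
        raise ParameterError("dunns_method requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise EmptyGroupError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    m = len(arrays) * (len(arrays) - 1) // 2
    results = []
    for i, j in combinations(range(len(arrays)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        results.append(
            TestResult(
                statistic=float(z),
                p_value=float(min(p, 1.0)),
                method="normal-approximation",
                pair=(labels[i], labels[j]),
                adjusted_p=float(min(m * p, 1.0)),
            )
        )
    return results


def significance_label(p: float) -> str:
    """Star convention: *** p<0.001, ** p<0.01, * p<0.05, else 'ns'."""
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
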