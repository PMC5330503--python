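"""Nonparametric group comparisons used throughout the analysis.

Thin, typed wrappers over scipy: two-sample Kolmogorov-Smirnov and
Wilcoxon/Mann-Whitney rank-sum tests, the Kruskal-Wallis omnibus test with
a Nemenyi post-hoc, and Spearman rank correlation.  All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ks_two_sample",
    "rank_sum",
    "kruskal_wallis_nemenyi",
    "spearman",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"sample {name} must be a non-empty 1-d array")
    return arr


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample KS test; exact null distribution when n*m <= 10,000."""
    xa, ya = _check_sample(x, "x"), _check_sample(y, "y")
    method = "exact" if xa.size * ya.size <= 10_000 else "asymp"
    res = sps.ks_2samp(xa, ya, method=method)
    return TestResult("kolmogorov_smirnov", float(res.statistic), float(res.pvalue),
                      (xa.size, ya.size))


def rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U (Wilcoxon rank-sum), two-sided.

    Exact when n+m <= 20 and there are no ties, otherwise the tie-corrected
    normal approximation.
    """
    xa, ya = _check_sample(x, "x"), _check_sample(y, "y")
    has_ties = np.unique(np.concatenate([xa, ya])).size < xa.size + ya.size
    method = "exact" if (xa.size + ya.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return TestResult("rank_sum", float(res.statistic), float(res.pvalue),
                      (xa.size, ya.size))


def kruskal_wallis_nemenyi(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    posthoc: str = "studentized_range",
) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) with a Nemenyi post-hoc.

    The post-hoc compares mean ranks of the pooled ranking.  With
    ``posthoc="studentized_range"`` (the common convention) the pairwise
    p-value comes from the studentized-range distribution with infinite
    degrees of freedom; ``posthoc="chisq"`` uses the chi-square variant
    with a tie correction.
    """
    arrs = [_check_sample(g, f"group{i}") for i, g in enumerate(groups)]
    if sum(a.size > 0 for a in arrs) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    h, p = sps.kruskal(*arrs)
    omnibus = TestResult("kruskal_wallis", float(h), float(p), tuple(a.size for a in arrs))

    pooled = np.concatenate(arrs)
    ranks = sps.rankdata(pooled)
    N = pooled.size
    k = len(arrs)
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    x_ties = 1.0 - (tie_counts**3 - tie_counts).sum() / (N**3 - N) if N > 1 else 1.0

    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks[i] - mean_ranks[j])
            se2 = (N * (N + 1) / 12.0) * (1.0 / arrs[i].size + 1.0 / arrs[j].size)
            if posthoc == "studentized_range":
                q = diff / np.sqrt(se2 / 2.0)
                pij = float(sps.studentized_range.sf(q, k, np.inf))
            elif posthoc == "chisq":
                stat = diff**2 / se2 / x_ties
                pij = float(sps.chi2.sf(stat, k - 1))
            else:
                raise ValueError(f"unknown posthoc {posthoc!r}")
            pmat.iloc[i, j] = pmat.iloc[j, i] = min(1.0, pij)
    return omnibus, pmat


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (average ranks under ties); statistic is rho."""
    xa, ya = _check_sample(x, "x"), _check_sample(y, "y")
    if xa.size != ya.size:
        raise ValueError("samples must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    rho, p = sps.spearmanr(xa, ya)
    return TestResult("spearman", float(rho), float(p), (xa.size, ya.size))
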