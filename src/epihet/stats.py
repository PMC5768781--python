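"""Shared statistical primitives.

The exact tests used throughout the pipeline live here so every module pins
the same conventions:

- Fisher's exact test on a 2x2 table is two-sided by the smallest-probability
  criterion: sum the hypergeometric probabilities of all tables (at fixed
  margins) no more likely than the observed one.
- Hypergeometric over-representation tests are one-sided upper tail,
  P(X >= k).
- Rank tests are exact for small tie-free inputs and fall back to the
  corrected normal approximation otherwise; degenerate inputs (zero
  variance / all-tied) report p = 1 rather than erroring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparisonResult:
    statistic: float
    pvalue: float
    test: str
    paired: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p).  The p-value sums hypergeometric tail
    probabilities of every table, at the observed margins, whose probability
    does not exceed that of the observed table (with a small relative slack
    for floating-point ties).  Odds ratio is the sample (cross-product)
    ratio, inf/nan for zero cells as conventional.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    n = a + b + c + d
    if n == 0:
        return np.nan, 1.0
    row1, col1 = a + b, a + c
    hg = sps.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hg.pmf(support)
    p_obs = hg.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def hypergeom_upper_tail(k: int, population: int, successes: int, draws: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population, successes, draws)."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("inconsistent hypergeometric parameters")
    return float(sps.hypergeom.sf(k - 1, population, successes, draws))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(a, b) -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact when tie-free."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in rank-sum test")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return GroupComparisonResult(np.nan, 1.0, "ranksum", degenerate=True)
    has_ties = len(np.unique(pooled)) < pooled.size
    n_assignments = math.comb(a.size + b.size, a.size)
    if not has_ties and a.size <= 25 and b.size <= 25:
        method = "exact"
    elif has_ties and n_assignments <= 20_000:
        # small tied samples: enumerate the permutation null exactly
        method = sps.PermutationMethod(n_resamples=n_assignments + 1)
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparisonResult(float(res.statistic), float(res.pvalue), "ranksum")


def signed_rank_test(a, b) -> GroupComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test requires equal-length vectors")
    diff = a - b
    if np.all(diff == 0.0):
        return GroupComparisonResult(np.nan, 1.0, "signedrank", paired=True,
                                     degenerate=True)
    res = sps.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
    return GroupComparisonResult(float(res.statistic), float(res.pvalue),
                                 "signedrank", paired=True)


def welch_t_test(a, b) -> GroupComparisonResult:
    """Two-sided Welch t-test; the parametric alternative exposed by flag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return GroupComparisonResult(np.nan, 1.0, "t", degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparisonResult(float(res.statistic), float(res.pvalue), "t")
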