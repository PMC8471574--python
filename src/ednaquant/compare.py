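"""Nonparametric and parametric group comparisons for eDNA concentrations.

Pairwise two-sided Wilcoxon rank-sum tests compare log10(x + 1) copy
concentrations among species, sampling events and stream classes (the test
is rank-based, so the transform does not change the result). Seasonal
inhibition delays are compared with a Welch t-test, and the delay-salinity
association with Spearman's rank correlation. Families of pairwise p-values
are adjusted with Holm's step-down procedure by default, and significance
stars follow the usual 0.05 / 0.01 / 0.001 / 0.0001 thresholds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))
ADJUST_METHODS = ("holm", "bonferroni", "none")


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group comparison."""

    group_a: str
    group_b: str
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float
    stars: str


def significance_stars(p: float) -> str:
    """Star code for a p-value: **** < 0.0001 ... * < 0.05, else ns."""
    if math.isnan(p):
        return "ns"
    for thr, code in STAR_THRESHOLDS:
        if p < thr:
            return code
    return "ns"


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have at most 10
    observations and there are no ties; otherwise the normal approximation
    with tie correction and a signed continuity correction (so two
    identical samples give p = 1). Returns (U statistic of the first
    group, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size <= 10 and b.size <= 10:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    n, m = a.size, b.size
    ranks = stats.rankdata(pooled)
    u1 = float(np.sum(ranks[:n]) - n * (n + 1) / 2)
    mu = n * m / 2.0
    nm = n + m
    sigma2 = n * m / 12.0 * (nm + 1 - _tie_term(pooled) / (nm * (nm - 1)))
    if sigma2 <= 0:  # every observation identical
        return u1, 1.0
    diff = u1 - mu
    z = (diff - math.copysign(0.5, diff) if diff != 0 else 0.0) / math.sqrt(sigma2)
    return u1, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def adjust_pvalues(p_raw: Sequence[float], method: str = "holm") -> np.ndarray:
    """Family-wise adjustment of a vector of p-values."""
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}; expected {ADJUST_METHODS}")
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0 or method == "none":
        return p.copy()
    return multipletests(p, method=method)[1]


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> pd.DataFrame:
    """All unordered pairwise rank-sum tests among named groups.

    Returns a frame with one row per pair: ``group_a``, ``group_b``,
    ``method``, ``statistic``, ``p_raw``, ``p_adjusted``, ``stars``. Stars
    are computed from the adjusted p-values when adjustment is on.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if len(np.asarray(groups[name])) < 1:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        u, p = rank_sum_test(groups[ga], groups[gb])
        rows.append({"group_a": ga, "group_b": gb, "method": "wilcoxon",
                     "statistic": u, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = adjust_pvalues(df["p_raw"], adjust)
    df["stars"] = df["p_adjusted"].map(significance_stars)
    return df


def two_sample_ttest(a, b) -> ComparisonResult:
    """Welch (unequal-variance) two-sided t-test.

    Two constant, equal groups give t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, np.mean(a) - np.mean(b))
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult("a", "b", "t_test", float(t), float(p), float(p),
                            significance_stars(float(p)))


def spearman_correlation(x, y) -> ComparisonResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks. The p-value is exact
    (full permutation enumeration) for n <= 8 and the t-approximation
    otherwise. Constant input yields an undefined (NaN) rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return ComparisonResult("x", "y", "spearman", math.nan, math.nan,
                                math.nan, "ns")
    rho, p_approx = stats.spearmanr(x, y)
    rho = float(rho)
    n = x.size
    if n <= 8:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    else:
        p = float(p_approx)
    return ComparisonResult("x", "y", "spearman", rho, p, p, significance_stars(p))
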