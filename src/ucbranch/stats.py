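"""Rank-based and exact statistical primitives.

Every test used downstream (Wilcoxon rank-sum, Kruskal-Wallis, Fisher's
exact 2x2, Benjamini-Hochberg, Spearman correlation, differential-panel
selection) is implemented here directly so that the conventions — two-sided
p-values, average ranks for ties, the probability-mass method for Fisher —
are explicit and checkable against enumeration oracles.  scipy supplies
only generic numerics (rank assignment and distribution tail functions).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm_dist
from scipy.stats import rankdata
from scipy.stats import t as _t_dist

__all__ = [
    "TestResult",
    "PanelDefinition",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "fisher_exact_2x2",
    "bh_adjust",
    "spearman",
    "differential_panel",
]

#: switch from exact enumeration to the normal approximation above this
#: pooled sample size
EXACT_MAX_N = 14


@dataclass
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    method: str
    effect: float | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _ranksum_exact_p(pooled_ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n1) group assignments."""
    n = len(pooled_ranks)
    total = 0
    lo = 0
    hi = 0
    tol = 1e-9
    for idx in itertools.combinations(range(n), n1):
        w = pooled_ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + tol:
            lo += 1
        if w >= w_obs - tol:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_rank_sum(
    x,
    y,
    mode: str = "auto",
    continuity: bool = True,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is the rank-sum W of ``x`` in the pooled sample with
    average ranks for ties.  Exact p-values enumerate all assignments of
    pooled values to the two groups (used when n1+n2 <= 14 in ``auto``
    mode); otherwise a tie-corrected normal approximation is used, with a
    continuity correction by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in {"auto", "exact", "approx"}:
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    w = float(ranks[:n1].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_MAX_N)
    if use_exact:
        p = _ranksum_exact_p(ranks, n1, w)
        return TestResult(statistic=w, p_value=p, method="exact")

    mean = n1 * (n + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(statistic=w, p_value=1.0, method="approx")
    diff = w - mean
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    z = diff / math.sqrt(var)
    p = min(1.0, 2.0 * float(_norm_dist.sf(abs(z))))
    return TestResult(statistic=w, p_value=p, method="approx")


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled, method="average")
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, method="approx")
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if correction <= 0:
        return TestResult(statistic=0.0, p_value=1.0, method="approx")
    h /= correction
    p = float(_chi2_dist.sf(h, len(groups) - 1))
    return TestResult(statistic=h, p_value=p, method="approx")


# ---------------------------------------------------------------------------
# Fisher's exact 2x2
# ---------------------------------------------------------------------------


def _log_hypergeom_pmf(k: int, n1: int, n2: int, m: int) -> float:
    # P(X = k) for X ~ Hypergeom(row1 total n1, row2 total n2, col1 total m)
    return (
        math.lgamma(n1 + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n1 - k + 1)
        + math.lgamma(n2 + 1)
        - math.lgamma(m - k + 1)
        - math.lgamma(n2 - (m - k) + 1)
        - (
            math.lgamma(n1 + n2 + 1)
            - math.lgamma(m + 1)
            - math.lgamma(n1 + n2 - m + 1)
        )
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test by the probability-mass method.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's (with a 1+1e-7 relative slack, the convention of R's
    ``fisher.test``).  The sample odds ratio is reported as the effect.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n1, n2, m = a + b, c + d, a + c
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if n1 == 0 or n2 == 0 or m == 0 or (b + d) == 0:
        return TestResult(statistic=float(a), p_value=1.0, method="exact", effect=odds)
    k_lo, k_hi = max(0, m - n2), min(n1, m)
    logp_obs = _log_hypergeom_pmf(a, n1, n2, m)
    cutoff = logp_obs + math.log1p(1e-7)
    p = 0.0
    for k in range(k_lo, k_hi + 1):
        lp = _log_hypergeom_pmf(k, n1, n2, m)
        if lp <= cutoff:
            p += math.exp(lp)
    return TestResult(statistic=float(a), p_value=min(1.0, p), method="exact", effect=odds)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

#: use the exact permutation p-value below this sample size
SPEARMAN_EXACT_N = 10


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average-tie ranks.

    p-value: t approximation for n >= 10, exact permutation of one rank
    vector for n < 10.  Constant input yields rho = p = NaN ("missing").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(statistic=math.nan, p_value=math.nan, method="undefined",
                          effect=math.nan)
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    rho = float(rxc @ ryc) / denom
    n = x.size
    if n >= SPEARMAN_EXACT_N:
        rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
        tstat = rho_c * math.sqrt((n - 2) / (1.0 - rho_c**2))
        p = min(1.0, 2.0 * float(_t_dist.sf(abs(tstat), n - 2)))
        method = "t-approx"
    else:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (rxc @ ryc[perms].T) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        method = "exact-perm"
    return TestResult(statistic=rho, p_value=p, method=method, effect=rho)


# ---------------------------------------------------------------------------
# Differential panel selection
# ---------------------------------------------------------------------------


@dataclass
class PanelDefinition:
    """Features up-regulated in each group plus the thresholds applied.

    Selection rule: BH-adjusted two-sided Wilcoxon p < alpha AND group-mean
    abundance ratio on the raw (linear) scale > fold_bounds[0] (up in A) or
    < fold_bounds[1] (up in B).
    """

    up_in_a: list[str]
    up_in_b: list[str]
    alpha: float
    fold_bounds: tuple[float, float]
    table: pd.DataFrame = field(repr=False, default=None)


def differential_panel(
    matrix: pd.DataFrame,
    labels: pd.Series,
    group_a,
    group_b,
    alpha: float = 0.05,
    fold_bounds: tuple[float, float] = (2.0, 0.5),
) -> PanelDefinition:
    """Select differential features between two sample groups.

    ``matrix`` is samples x features on the log2 scale (imputed); testing
    is on log2 values, fold change is the ratio of group means on the
    linear scale recovered as ``2**value`` (imputed floor values included).
    """
    labels = labels.loc[matrix.index]
    in_a = labels == group_a
    in_b = labels == group_b
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise ValueError("both groups need >= 3 samples")
    xa = matrix.loc[in_a].to_numpy(dtype=float)
    xb = matrix.loc[in_b].to_numpy(dtype=float)
    lin_a = np.power(2.0, xa).mean(axis=0)
    lin_b = np.power(2.0, xb).mean(axis=0)
    ratio = lin_a / lin_b
    pvals = np.array(
        [wilcoxon_rank_sum(xa[:, j], xb[:, j]).p_value for j in range(matrix.shape[1])]
    )
    qvals = bh_adjust(pvals)
    sig = qvals < alpha
    up_a = sig & (ratio > fold_bounds[0])
    up_b = sig & (ratio < fold_bounds[1])
    table = pd.DataFrame(
        {
            "feature": matrix.columns,
            "p": pvals,
            "q": qvals,
            "fold_change": ratio,
            "direction": np.where(up_a, "up_in_a", np.where(up_b, "up_in_b", "ns")),
        }
    ).set_index("feature")
    panel = PanelDefinition(
        up_in_a=list(matrix.columns[up_a]),
        up_in_b=list(matrix.columns[up_b]),
        alpha=alpha,
        fold_bounds=fold_bounds,
        table=table,
    )
    if not panel.up_in_a and not panel.up_in_b:
        warnings.warn("no feature passed the panel thresholds", stacklevel=2)
    return panel


def write_results_tsv(table: pd.DataFrame, path) -> None:
    """Write a per-feature result table (statistic, p, q, fold change)."""
    table.to_csv(path, sep="\t")
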