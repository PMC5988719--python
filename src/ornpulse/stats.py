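"""Nonparametric statistics with exact small-sample behavior.

Wilcoxon rank-sum (exact permutation distribution with mid-ranks, or a
tie- and continuity-corrected normal approximation), Fisher's exact
test (two-sided, probability-mass rule), Bonferroni and
Benjamini-Hochberg p-value adjustment, and box-plot five-number
summaries.

Quantiles use linear interpolation between order statistics (numpy's
default, the common "type 7" convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "StatResult",
    "BoxSummary",
    "rank_sum_test",
    "fisher_exact_test",
    "adjust_pvalues",
    "box_summary",
]

EXACT_MAX_N = 20  # combined sample size up to which 'auto' uses the exact mode


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    adjust_method: str = "none"
    n_per_group: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p below raw p")

    def with_adjusted(self, p_adj: float, method: str) -> "StatResult":
        return StatResult(
            self.test_name, self.statistic, self.p_raw, p_adj, method, self.n_per_group
        )


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _ranksum_exact_p(ranks2: np.ndarray, n1: int, w2_obs: float) -> float:
    """Exact two-sided p for the rank sum, by counting subsets.

    ``ranks2`` are pooled mid-ranks doubled (integers), ``w2_obs`` the
    doubled observed rank sum of the first sample. The null distribution
    over all C(N, n1) equally likely subsets is built by subset-sum
    dynamic programming; two-sided p sums the probability of rank sums
    at least as far from the null mean as observed.
    """
    N = ranks2.size
    total2 = int(ranks2.sum())
    max_s = total2
    # dp[k][s] = number of k-subsets of the processed ranks summing to s
    dp = np.zeros((n1 + 1, max_s + 1), dtype=np.float64)
    dp[0][0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n1, 0, -1):  # descending: row k-1 not yet updated for this r
            dp[k, r:] += dp[k - 1, 0 : max_s + 1 - r]
    counts = dp[n1]
    n_subsets = counts.sum()
    mu2 = n1 * total2 / N
    dev = abs(w2_obs - mu2)
    s = np.arange(max_s + 1)
    extreme = np.abs(s - mu2) >= dev - 1e-9
    return float(counts[extreme].sum() / n_subsets)


def _ranksum_approx_p(ranks: np.ndarray, n1: int, w_obs: float) -> tuple[float, float]:
    """Normal approximation with tie and continuity corrections.

    Returns (z, p). σ² includes the standard tie correction based on
    the sizes of tied groups in the pooled sample.
    """
    N = ranks.size
    n2 = N - n1
    mu = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 0.0, 1.0
    diff = w_obs - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var)
    return float(z), float(min(1.0, 2.0 * norm.sf(abs(z))))


def rank_sum_test(x, y, mode: str = "auto") -> StatResult:
    """Two-sided Wilcoxon rank-sum test.

    mode='exact' enumerates the permutation distribution of the rank sum
    (mid-ranks for ties); mode='approx' uses the normal approximation
    with tie and continuity corrections; mode='auto' picks exact for
    combined n <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; rank-sum p = 1", stacklevel=2)
        return StatResult("ranksum", w, 1.0, n_per_group=(x.size, y.size))
    if mode == "auto":
        mode = "exact" if pooled.size <= EXACT_MAX_N else "approx"
    if mode == "exact":
        ranks2 = np.rint(ranks * 2).astype(np.int64)  # mid-ranks doubled -> integers
        p = _ranksum_exact_p(ranks2, x.size, 2.0 * w)
    elif mode == "approx":
        _, p = _ranksum_approx_p(ranks, x.size, w)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StatResult("ranksum", w, min(p, 1.0), n_per_group=(x.size, y.size))


# ---------------------------------------------------------------------------
# Fisher's exact test

_REL_TOL = 1.0 + 1e-7  # tolerance when comparing table probabilities


def _log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    return (
        math.lgamma(K + 1)
        - math.lgamma(k + 1)
        - math.lgamma(K - k + 1)
        + math.lgamma(N - K + 1)
        - math.lgamma(n - k + 1)
        - math.lgamma(N - K - n + k + 1)
        - (math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1))
    )


def fisher_exact_test(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    p is the sum of hypergeometric probabilities, over all tables with
    the observed margins, of tables whose probability does not exceed
    the observed table's (within a 1 + 1e-7 relative tolerance) — the
    probability-mass convention of mainstream implementations.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t != np.rint(t)) or np.any(t < 0):
        raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = (int(v) for v in np.rint(t).ravel())
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    N = r1 + r2
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        warnings.warn("degenerate 2x2 table (zero margin); Fisher p = 1", stacklevel=2)
        return StatResult("fisher_exact", odds, 1.0, n_per_group=(r1, r2))
    kmin = max(0, r1 - c2)
    kmax = min(r1, c1)
    logp = np.array([_log_hypergeom_pmf(k, N, c1, r1) for k in range(kmin, kmax + 1)])
    p_obs = math.exp(_log_hypergeom_pmf(a, N, c1, r1))
    p = float(np.exp(logp)[np.exp(logp) <= p_obs * _REL_TOL].sum())
    return StatResult("fisher_exact", odds, min(p, 1.0), n_per_group=(r1, r2))


# ---------------------------------------------------------------------------
# multiple-testing adjustment


def adjust_pvalues(p_list, method: str, m: int | None = None) -> list[float]:
    """Adjust p-values for multiple comparisons.

    method='bonferroni': min(1, m * p) per test. method='benjamini_hochberg':
    step-up adjusted values, monotone in the sorted order, capped at 1.
    ``m`` defaults to len(p_list) but may be set larger when the battery
    includes comparisons not passed here.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    if method == "bonferroni":
        return list(np.minimum(1.0, m * p))
    if method == "benjamini_hochberg":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        # enforce monotonicity from the largest rank downwards
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty_like(adj)
        out[order] = adj
        return list(out)
    if method == "none":
        return list(p)
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# box-plot summaries


def box_summary(sample, whisker_rule: str = "tukey") -> BoxSummary:
    """Five-number box-plot summary.

    whisker_rule='tukey': whiskers reach the most extreme data points
    within 1.5 IQR of the box; points beyond are outliers.
    whisker_rule='range': whiskers span the full data range and the
    outlier list is empty (some figure legends describe whiskers as the
    data range while still drawing outlier circles; both conventions
    are provided).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one observation")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    if whisker_rule == "range":
        return BoxSummary(float(med), float(q1), float(q3), float(x.min()), float(x.max()), [])
    if whisker_rule != "tukey":
        raise ValueError(f"unknown whisker rule {whisker_rule!r}")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    # whiskers never retreat inside the box (interpolated quartiles can
    # exceed every non-outlier data point in tiny samples)
    wl = min(float(inside.min()), float(q1)) if inside.size else float(q1)
    wh = max(float(inside.max()), float(q3)) if inside.size else float(q3)
    outliers = sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxSummary(float(med), float(q1), float(q3), wl, wh, outliers)
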