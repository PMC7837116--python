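"""Statistical procedures shared by the connectivity, calcium and behavior stages.

Thin, explicitly-parameterized wrappers around scipy/statsmodels: every result
carries its method metadata (alternative, correction, exact vs. approximate) so
a reported comparison can be reproduced without guessing defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TestResult",
    "chi_square_proportions",
    "wilcoxon_rank_sum",
    "t_test",
    "proportion_ci",
]

TWO_SIDED = "two_sided"
GREATER = "greater"
LESS = "less"
_ALTERNATIVES = (TWO_SIDED, GREATER, LESS)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str
    n: tuple[int, ...]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _check_alternative(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    return alternative


def chi_square_proportions(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square test of homogeneity on a k x 2 count table.

    Rows are groups, columns are (event, non-event) counts. Yates continuity
    correction is applied only when requested and the table is 2 x 2. Any
    zero expected cell count is an error (the asymptotic test is invalid there).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("expected a k x 2 table with k >= 2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("zero marginal total: expected counts are zero")
    stat, p, dof, _ = stats.chi2_contingency(
        table, correction=continuity and table.shape[0] == 2
    )
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        alternative=TWO_SIDED,
        method=f"chi_square_proportions(df={dof}, continuity={continuity})",
        n=tuple(int(r) for r in table.sum(axis=1)),
    )


_TAIL_EXACT_SPAN = 10  # exact tail evaluation within this distance of the support edge


def _bounded_partition_counts(k: int, m: int, n: int) -> list[int]:
    """counts[j] = partitions of j into at most m parts, each at most n.

    This is the exact number of rank assignments with Mann-Whitney statistic
    U = j, so lower-tail probabilities P(U <= k) are exact for tie-free data
    at any sample size (only small k is ever needed).
    """
    from functools import lru_cache

    max_part = min(n, k)
    max_count = min(m, k)

    @lru_cache(maxsize=None)
    def count(j: int, parts: int, largest: int) -> int:
        if j == 0:
            return 1
        if parts == 0 or largest == 0:
            return 0
        return sum(count(j - s, parts - 1, s) for s in range(1, min(largest, j) + 1))

    return [count(j, max_count, max_part) for j in range(k + 1)]


def _exact_lower_tail(k: int, m: int, n: int) -> float:
    """P(U <= k) under the tie-free null, exact for any m, n."""
    if k < 0:
        return 0.0
    if k >= m * n:
        return 1.0
    counts = _bounded_partition_counts(k, m, n)
    from fractions import Fraction
    from math import comb

    return float(Fraction(sum(counts), comb(m + n, m)))


def _edgeworth_sf(z: float, g2: float) -> float:
    """Upper tail of the standardized null with a kurtosis correction."""
    return float(
        stats.norm.sf(z) + stats.norm.pdf(z) * (g2 / 24.0) * (z**3 - 3.0 * z)
    )


def _approx_sf(u: float, m: int, n: int, sd: float, g2: float, tie_free: bool) -> float:
    """P(U >= u): exact near the support edges (tie-free), else corrected normal."""
    if u <= 0:
        return 1.0
    if tie_free:
        ui = int(round(u))
        if ui - 1 <= _TAIL_EXACT_SPAN:
            return 1.0 - _exact_lower_tail(ui - 1, m, n)
        if m * n - ui <= _TAIL_EXACT_SPAN:
            return _exact_lower_tail(m * n - ui, m, n)  # symmetry of the null
    z = (u - 0.5 - m * n / 2.0) / sd
    return min(1.0, max(0.0, _edgeworth_sf(z, g2)))


def wilcoxon_rank_sum(
    x,
    y,
    alternative: str = TWO_SIDED,
    exact_max_n: int = 12,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    The p-value is exact (full enumeration of rank assignments) when the
    combined sample size is at most ``exact_max_n`` and there are no ties.
    Otherwise a refined normal approximation is used: continuity correction,
    tie-corrected variance, an Edgeworth kurtosis term, and exact tail
    probabilities (bounded-partition counts) within a few steps of the
    support boundary, where the normal body is weakest. With ties the
    kurtosis term uses the tie-free fourth cumulant (the correction is
    O(1/n) and insensitive to moderate ties).
    """
    alternative = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    m, n = int(x.size), int(y.size)
    total = m + n
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = float(ranks[:m].sum())
    u = r_x - m * (m + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_free = bool((tie_counts == 1).all())

    if total <= exact_max_n and tie_free:
        scipy_alt = {TWO_SIDED: "two-sided", GREATER: "greater", LESS: "less"}
        res = stats.mannwhitneyu(x, y, alternative=scipy_alt[alternative], method="exact")
        return TestResult(
            statistic=r_x,
            p_value=float(min(res.pvalue, 1.0)),
            alternative=alternative,
            method="wilcoxon_rank_sum(exact)",
            n=(m, n),
        )

    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (total * (total - 1)))
    var = m * n / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return TestResult(r_x, 1.0, alternative, "wilcoxon_rank_sum(degenerate)", (m, n))
    sd = np.sqrt(var)
    g2 = -6.0 * (m * m + n * n + m * n + m + n) / (5.0 * m * n * (total + 1))
    p_greater = _approx_sf(u, m, n, sd, g2, tie_free)
    p_less = _approx_sf(m * n - u, m, n, sd, g2, tie_free)
    if alternative == GREATER:
        p = p_greater
    elif alternative == LESS:
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(
        statistic=r_x,
        p_value=p,
        alternative=alternative,
        method="wilcoxon_rank_sum(normal_approx)",
        n=(m, n),
    )


def t_test(
    x,
    y=None,
    mu: float = 0.0,
    alternative: str = TWO_SIDED,
    pooled: bool = False,
) -> TestResult:
    """One-sample t test against ``mu`` or (default Welch) two-sample t test.

    Degenerate zero-variance inputs follow the convention: zero effect gives
    p = 1, nonzero effect gives p = 0 (and an infinite statistic).
    """
    alternative = _check_alternative(alternative)
    scipy_alt = {TWO_SIDED: "two-sided", GREATER: "greater", LESS: "less"}[alternative]
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if y is None:
        if np.ptp(x) == 0.0:
            return _degenerate_t(float(x[0] - mu), alternative, (x.size,), "one_sample")
        res = stats.ttest_1samp(x, popmean=mu, alternative=scipy_alt)
        n: tuple[int, ...] = (int(x.size),)
        method = f"t_test(one_sample, mu={mu})"
    else:
        y = np.asarray(y, dtype=float)
        if y.size < 2:
            raise ValueError("need at least 2 observations per sample")
        if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
            return _degenerate_t(
                float(x[0] - y[0]), alternative, (x.size, y.size), "two_sample"
            )
        res = stats.ttest_ind(x, y, equal_var=pooled, alternative=scipy_alt)
        n = (int(x.size), int(y.size))
        method = f"t_test({'pooled' if pooled else 'welch'})"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        method=method,
        n=n,
    )


def _degenerate_t(effect, alternative, n, which) -> TestResult:
    if effect == 0.0:
        stat, p = 0.0, 1.0
    else:
        stat = math_inf_signed(effect)
        if alternative == TWO_SIDED:
            p = 0.0
        elif alternative == GREATER:
            p = 0.0 if effect > 0 else 1.0
        else:
            p = 0.0 if effect < 0 else 1.0
    return TestResult(
        statistic=stat,
        p_value=p,
        alternative=alternative,
        method=f"t_test({which}, zero_variance)",
        n=n,
    )


def math_inf_signed(v: float) -> float:
    return float("inf") if v > 0 else float("-inf")


def proportion_ci(
    successes: int, n: int, method: str = "wilson", level: float = 0.95
) -> tuple[float, float]:
    """Two-sided confidence interval for a binomial proportion.

    Wilson score interval by default (well-behaved at 0 and n); the Wald
    (normal) interval is available for comparison with older reports.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n with n > 0")
    if method not in ("wilson", "wald"):
        raise ValueError("method must be 'wilson' or 'wald'")
    lo, hi = proportion_confint(
        successes, n, alpha=1.0 - level, method="wilson" if method == "wilson" else "normal"
    )
    # boundary cases are exact by construction for the Wilson interval
    if successes == 0:
        lo = 0.0
    if successes == n and method == "wilson":
        hi = 1.0
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
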