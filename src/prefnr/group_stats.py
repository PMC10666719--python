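"""Response-feature statistics across hearing-loss groups.

Each participant's repeated paired-comparison responses are reduced to a
single feature — the preferred noise-reduction strength — and that feature is
compared across groups with nonparametric machinery: normality screening
(Kolmogorov–Smirnov), homoscedasticity (Bartlett), the Kruskal–Wallis rank
test, Dunn's Bonferroni-corrected post hoc z-tests on mean ranks, and
Spearman correlations against hearing-loss covariates.  The design-stage
power calculation that sized the study groups lives here too.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "PowerSpec",
    "PairwiseResult",
    "ks_normal_test",
    "bartlett_test",
    "kruskal_wallis",
    "dunn_bonferroni",
    "spearman_correlation",
    "power_sample_size",
    "DegenerateSampleError",
]


class DegenerateSampleError(ValueError):
    """A sample without enough variation for the requested test."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn post hoc comparison between two groups."""

    pair: tuple[int, int]
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample power-calculation inputs.

    sigma: within-group SD of the preference feature, dB.
    delta: smallest group difference worth detecting, dB.
    alpha: two-sided type-I level; power: target power (e.g. 0.80).
    """

    sigma: float
    delta: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.delta <= 0:
            raise ValueError("sigma and delta must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def ks_normal_test(
    values,
    mu: float | None = None,
    sigma: float | None = None,
    lilliefors: bool = False,
) -> TestResult:
    """One-sample KS test of normality.

    By default the reference normal uses the sample mean and SD and the
    p-value comes from the asymptotic KS distribution (the plain KS usage,
    which is anti-conservative when parameters are estimated).  Passing
    ``lilliefors=True`` applies the Lilliefors correction instead; ``mu`` and
    ``sigma`` may also be supplied to test against a fully specified normal.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    estimated = mu is None or sigma is None
    if estimated or lilliefors:
        # estimating (mu, sigma) from the sample needs a non-degenerate sample
        if x.size < 3:
            raise DegenerateSampleError("need at least 3 values")
        if np.std(x) == 0:
            raise DegenerateSampleError("zero sample variance")
    elif x.size < 1:
        raise DegenerateSampleError("empty sample")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(x, dist="norm")
        return TestResult(float(d), float(min(p, 1.0)), "KS (Lilliefors)")
    if mu is None:
        mu = float(np.mean(x))
    if sigma is None:
        sigma = float(np.std(x, ddof=1))
    d, p = stats.kstest(x, "norm", args=(mu, sigma))
    return TestResult(float(d), float(p), "KS vs normal")


def bartlett_test(groups) -> TestResult:
    """Bartlett's test for equal variances across groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
        if np.var(g) == 0:
            raise DegenerateSampleError(f"group {i} has zero variance")
    stat, p = stats.bartlett(*arrays)
    return TestResult(float(stat), float(p), "Bartlett", df=len(arrays) - 1)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H test (mid-rank ties correction, chi-square p).

    An all-identical pooled sample carries no rank information; it returns
    H = 0, p = 1 rather than the 0/0 the tie correction would produce.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "Kruskal-Wallis", df=df)
    stat, p = stats.kruskal(*arrays)
    return TestResult(float(stat), float(p), "Kruskal-Wallis", df=df)


def dunn_bonferroni(groups, alpha: float = 0.05, m: int | None = None) -> list[PairwiseResult]:
    """Dunn's post hoc z-tests on pooled mean ranks, Bonferroni corrected.

    Groups are ranked jointly with mid-ranks; the z statistic for groups i, j
    is (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    correction T = Σ(t³−t)/(12(N−1)).  Two-sided p-values are multiplied by
    ``m`` (default: the number of pairs) and capped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    if m is None:
        m = len(pairs)
    if m < len(pairs):
        raise ValueError(f"m={m} smaller than the {len(pairs)} pairwise comparisons")

    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[bounds[i] : bounds[i + 1]])) for i in range(len(arrays))
    ]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    results = []
    for i, j in pairs:
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = float(min(1.0, p_raw * m))
        results.append(
            PairwiseResult((i, j), float(z), float(p_raw), p_adj, bool(p_adj < alpha))
        )
    return results


def _exact_spearman_p(rho_obs: float, rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided permutation p-value for Spearman rho (feasible for n <= 9)."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = float(rx_c @ ry_c[list(perm)]) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def spearman_correlation(x, y, exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with missing-pair dropping.

    Pairs where either member is missing (NaN/None) are removed first —
    matching how absent SRT measurements are handled.  The p-value uses the
    exact permutation distribution for small n (<= ``exact_max_n``) and the
    t-approximation t = rho * sqrt((n−2)/(1−rho²)) otherwise.
    """
    x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise DegenerateSampleError(f"need at least 4 complete pairs, have {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry)[0])
    if n <= exact_max_n:
        p = _exact_spearman_p(rho, rx, ry)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return TestResult(rho, min(p, 1.0), "Spearman", df=n - 2)


def power_sample_size(spec: PowerSpec, method: str = "normal") -> int:
    """Per-group sample size for a two-sample comparison of means.

    ``normal`` (default) is the normal-approximation formula

        n = 2 sigma^2 (z_{1-alpha/2} + z_{power})^2 / delta^2

    rounded to the *nearest* integer — the convention that yields 8 per group
    for sigma = 1.8 dB, delta = 2.5 dB, alpha = 0.05, power = 0.80.
    ``exact-t`` uses the noncentral-t power of the two-sample t-test (ceiling)
    and is stricter, typically one or two participants larger.
    """
    if method == "normal":
        z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
        z_b = stats.norm.ppf(spec.power)
        n = 2.0 * spec.sigma**2 * (z_a + z_b) ** 2 / spec.delta**2
        return max(1, round(n))
    if method == "exact-t":
        from statsmodels.stats.power import TTestIndPower

        n = TTestIndPower().solve_power(
            effect_size=spec.delta / spec.sigma,
            alpha=spec.alpha,
            power=spec.power,
            alternative="two-sided",
        )
        return max(2, math.ceil(n))
    raise ValueError(f"unknown method {method!r}")
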