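"""Statistical toolkit for the fracture-healing animal study.

Covers the analyses applied to the experimental arm: radiographic
scoring of fracture healing (three ordinal categories, maximum total 8),
pooled two-sample Student's t from group summaries with a 95 % CI,
Mann-Whitney U for ordinal scores (mid-rank ties; exact permutation p for
small samples, tie-corrected normal approximation otherwise), Cohen's
kappa for inter-observer agreement, a Lilliefors-style Kolmogorov-Smirnov
normality check with simulated p, and a priori sample sizing from
Cohen's d via the noncentral-t power function.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RadiographScore",
    "GroupSummary",
    "TestResult",
    "score_radiograph",
    "pooled_t_test",
    "mann_whitney_u",
    "cohens_kappa",
    "ks_normality",
    "sample_size_cohens_d",
    "two_sample_t_power",
]

# (category, max score): periosteal reaction and bone union run 0-3,
# remodeling 0-2, so a fully healed fracture totals 8.
SCORE_RANGES = {"periosteal": 3, "union": 3, "remodeling": 2}
MAX_TOTAL_SCORE = sum(SCORE_RANGES.values())


@dataclass(frozen=True)
class RadiographScore:
    periosteal: int
    union: int
    remodeling: int

    def __post_init__(self) -> None:
        for cat, hi in SCORE_RANGES.items():
            v = getattr(self, cat)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= hi):
                raise ValueError(f"{cat} score must be an integer in [0, {hi}], got {v!r}")

    @property
    def total(self) -> int:
        return int(self.periosteal + self.union + self.remodeling)


def score_radiograph(periosteal: int, union: int, remodeling: int) -> RadiographScore:
    """Validate and assemble one radiographic healing score."""
    return RadiographScore(periosteal, union, remodeling)


@dataclass(frozen=True)
class GroupSummary:
    """(mean, SD, n) summary of one group's measurements."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.ci_low is not None and self.ci_high is not None and self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")


def pooled_t_test(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Equal-variance two-sample t test from group summaries.

    Returns t, df = n_a + n_b - 2, the 95 % CI on mean(a) - mean(b), and
    the two-sided p.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    diff = a.mean - b.mean
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, df=df, ci_low=0.0, ci_high=0.0, method="pooled t")
        raise ValueError("zero pooled variance with unequal means")
    se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    return TestResult(
        statistic=t, p=p, df=df,
        ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
        method="pooled t",
    )


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U_x, U_y) by the rank-sum formula with mid-rank ties."""
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx = ranks[:nx].sum()
    ux = nx * ny + nx * (nx + 1) / 2.0 - rx
    return ux, nx * ny - ux


def mann_whitney_u(x, y, exact_max_n: int = 8) -> TestResult:
    """Mann-Whitney U test with mid-rank tie handling.

    The reported statistic is min(U_x, U_y).  The two-sided p comes from
    exact enumeration of the permutation distribution when
    ``min(n_x, n_y) <= exact_max_n``, otherwise from the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    ux, uy = _rank_sum_u(x, y)
    u = min(ux, uy)
    mu = nx * ny / 2.0

    if min(nx, ny) <= exact_max_n and math.comb(nx + ny, nx) <= 200_000:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        dev_obs = abs(ux - mu)
        count = 0
        total = 0
        for comb in itertools.combinations(range(nx + ny), nx):
            rx = ranks[list(comb)].sum()
            u_perm = nx * ny + nx * (nx + 1) / 2.0 - rx
            if abs(u_perm - mu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        p = count / total
        method = "Mann-Whitney U (exact permutation)"
    else:
        n = nx + ny
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (abs(ux - mu) - 0.5) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(max(z, 0.0))
        p = min(p, 1.0)
        method = "Mann-Whitney U (normal approx., tie-corrected)"
    return TestResult(statistic=u, p=p, method=method)


def cohens_kappa(r1, r2) -> float:
    """Cohen's kappa between two raters: (p_o - p_e) / (1 - p_e)."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rating vectors must be 1D and of equal length")
    n = len(r1)
    if n == 0:
        raise ValueError("empty rating vectors")
    cats = np.union1d(r1, r2)
    p_o = float(np.mean(r1 == r2))
    p1 = np.array([np.mean(r1 == c) for c in cats])
    p2 = np.array([np.mean(r2 == c) for c in cats])
    p_e = float(np.sum(p1 * p2))
    if p_e >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1 (both raters constant)")
    return (p_o - p_e) / (1.0 - p_e)


def _lilliefors_stat(x: np.ndarray) -> float:
    n = len(x)
    mu = x.mean()
    sd = x.std(ddof=1)
    z = np.sort((x - mu) / sd)
    cdf = sps.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(ecdf_hi - cdf, cdf - ecdf_lo)))


def ks_normality(sample, n_sim: int = 2000, seed: int = 0) -> TestResult:
    """Kolmogorov-Smirnov normality test with estimated mean and SD.

    The plug-in of sample moments invalidates the classical KS null
    distribution, so the p value is obtained by Monte-Carlo simulation
    (Lilliefors approach): ``n_sim`` standard-normal samples of the same
    size, seeded for reproducibility.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("constant sample")
    d = _lilliefors_stat(x)
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_sim, len(x)))
    d_sim = np.array([_lilliefors_stat(s) for s in sims])
    p = float((np.sum(d_sim >= d) + 1) / (n_sim + 1))
    return TestResult(statistic=d, p=p, method="KS normality (Lilliefors, simulated p)")


def two_sample_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at ``n`` per group."""
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_cohens_d(d: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest per-group n with two-sample t power at least ``power``."""
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, 100000):
        if two_sample_t_power(n, d, alpha) >= power:
            return n
    raise RuntimeError("sample size search did not converge")
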