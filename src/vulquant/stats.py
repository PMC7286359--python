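"""Induction scoring and the hypothesis-test battery.

The vulval induction index (VI) is the total number of induced VPCs
divided by the number of animals scored; a wild-type animal has exactly
three induced VPCs (P5.p, P6.p, P7.p), so VI = 3 in the wild-type.
Per-animal counts above/below 3 classify hyper-/hypo-induction.

Uncertainty on cohort means is estimated by bootstrap resampling: the SD
of the resample means is the SEM estimate; the 95% CI defaults to the
2.5/97.5 percentiles of the resample means (a normal-approximation
interval, point ± 1.96·SEM, is available as an option).

Fisher's exact test and the Mann-Whitney U test are implemented here
directly: Fisher as the sum of hypergeometric probabilities not exceeding
the observed table's; Mann-Whitney exactly by permutation enumeration
(mid-ranks for ties) when the combined sample size is at most 12, and by
the tie-corrected normal approximation with continuity correction
otherwise.  The t-test variants delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from vulquant.errors import DegenerateInputError, VulquantError

__all__ = [
    "InductionCohort",
    "BootstrapResult",
    "vulval_index",
    "classify_induction",
    "bootstrap_mean",
    "fate_shift_table",
    "welch_t",
    "student_t",
    "mann_whitney_u",
    "f_test_variance",
    "fisher_exact",
]

#: Maximum combined sample size for the exact Mann-Whitney enumeration.
MW_EXACT_LIMIT = 12


@dataclass(frozen=True)
class InductionRecord:
    animal_id: str
    genotype: str
    induced_count: float
    primary_fate_vpc: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.induced_count <= 6:
            raise VulquantError(
                f"{self.animal_id}: induced_count {self.induced_count} "
                "outside [0, 6] (six VPCs)"
            )
        if (2 * self.induced_count) % 1 != 0:
            raise VulquantError(
                f"{self.animal_id}: induced_count must be a multiple of 0.5"
            )


@dataclass
class InductionCohort:
    """Scored animals of one genotype/condition."""

    records: list[InductionRecord]

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.induced_count for r in self.records], dtype=float)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    sem: float
    ci95: tuple[float, float]
    n_resamples: int
    seed: int | None
    ci_method: str = "percentile"


def vulval_index(cohort: InductionCohort) -> float:
    """Total induced cells divided by the number of animals scored."""
    if len(cohort) == 0:
        raise VulquantError("empty induction cohort")
    return float(cohort.counts.sum() / len(cohort))


def classify_induction(record: "InductionRecord | float") -> str:
    """Per-animal induction phenotype by strict comparison against 3."""
    count = record.induced_count if isinstance(record, InductionRecord) else record
    if count > 3:
        return "hyperinduced"
    if count < 3:
        return "hypo-induced"
    return "wild-type"


def bootstrap_mean(
    values: "np.ndarray | list[float]",
    n_resamples: int = 10_000,
    seed: int | None = None,
    ci_method: str = "percentile",
) -> BootstrapResult:
    """Bootstrap the mean of ``values``.

    Draws ``n_resamples`` resamples of size n with replacement; the point
    estimate is the sample mean, the SEM is the SD of the resample means
    and the 95% CI is percentile-based by default (``ci_method="normal"``
    gives point ± 1.96·SEM).  Deterministic for a fixed seed.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise VulquantError("cannot bootstrap an empty sample")
    if ci_method not in ("percentile", "normal"):
        raise VulquantError(f"unknown ci_method {ci_method!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_resamples, arr.size))
    means = arr[idx].mean(axis=1)
    point = float(arr.mean())
    sem = float(means.std(ddof=1))
    if ci_method == "percentile":
        lo, hi = np.percentile(means, [2.5, 97.5])
    else:
        lo, hi = point - 1.96 * sem, point + 1.96 * sem
    return BootstrapResult(
        point_estimate=point,
        sem=sem,
        ci95=(float(lo), float(hi)),
        n_resamples=n_resamples,
        seed=seed,
        ci_method=ci_method,
    )


def fate_shift_table(cohort: InductionCohort) -> dict:
    """Counts of the primary (1°) fate at P5.p / P6.p / P7.p.

    Returns the per-VPC counts and the percentage of animals whose primary
    fate shifted away from P6.p.
    """
    if len(cohort) == 0:
        raise VulquantError("empty induction cohort")
    allowed = ("P5.p", "P6.p", "P7.p")
    counts = {lbl: 0 for lbl in allowed}
    for rec in cohort.records:
        if rec.primary_fate_vpc not in allowed:
            raise VulquantError(
                f"{rec.animal_id}: primary fate VPC "
                f"{rec.primary_fate_vpc!r} not in {allowed}"
            )
        counts[rec.primary_fate_vpc] += 1
    n = len(cohort)
    shifted = n - counts["P6.p"]
    return {**counts, "n": n, "percent_shifted": 100.0 * shifted / n}


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def _check_two_samples(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < min_n or y.size < min_n:
        raise VulquantError(
            f"each sample needs >= {min_n} values; got {x.size} and {y.size}"
        )
    return x, y


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided t-test for independent samples of unequal variance.

    Uses the Welch-Satterthwaite degrees of freedom.
    """
    x, y = _check_two_samples(x, y, 2)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise DegenerateInputError("both samples have zero variance")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def student_t(x, y) -> tuple[float, float]:
    """Two-sided t-test for independent samples of equal variance."""
    x, y = _check_two_samples(x, y, 2)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise DegenerateInputError("both samples have zero variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: pairs where x beats y, ties counted half."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Exact permutation enumeration over all rank assignments (mid-ranks for
    ties) when n + m <= 12; otherwise the normal approximation with tie
    correction and continuity correction.  The two-sided p counts
    permutations whose U deviates from the null mean n·m/2 at least as far
    as observed.
    """
    x, y = _check_two_samples(x, y, 1)
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n * m / 2.0
    if n + m <= MW_EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)  # mid-ranks for ties
        dev_obs = abs(u_obs - mu)
        total = comb(n + m, n)
        hits = 0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    # Normal approximation with tie correction.
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    N = n + m
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    sigma2 = n * m / 12.0 * (N + 1 - tie_term)
    if sigma2 == 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)  # continuity correction
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return u_obs, p


def f_test_variance(x, y) -> tuple[float, float]:
    """Two-sided F-test for equality of variances.

    F is the larger sample variance over the smaller; p doubles the tail
    beyond F with matched degrees of freedom (capped at 1).
    """
    x, y = _check_two_samples(x, y, 2)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateInputError("zero variance in an F-test sample")
    if vx >= vy:
        f, dfn, dfd = vx / vy, x.size - 1, y.size - 1
    else:
        f, dfn, dfd = vy / vx, y.size - 1, x.size - 1
    tail = float(sps.f.sf(f, dfn, dfd))
    return float(f), min(1.0, 2.0 * tail)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (within a 1 + 1e-7 relative factor to absorb floating-point ties).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise VulquantError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise VulquantError("table cells must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, col1, n - row1, n - col1) <= 0 or n == 0:
        raise VulquantError("Fisher's exact test requires positive margins")
    k_lo = max(0, row1 + col1 - n)
    k_hi = min(row1, col1)
    support = np.arange(k_lo, k_hi + 1)
    pmf = sps.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - k_lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(1.0, p)
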