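from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from vulquant.errors import DegenerateInputError, VulquantError
from vulquant.stats import (
    InductionCohort,
    InductionRecord,
    bootstrap_mean,
    classify_induction,
    f_test_variance,
    fate_shift_table,
    fisher_exact,
    mann_whitney_u,
    student_t,
    vulval_index,
    welch_t,
)


def cohort_from_counts(counts, primaries=None):
    primaries = primaries or [None] * len(counts)
    return InductionCohort([
        InductionRecord(f"a{i}", "wt", c, p)
        for i, (c, p) in enumerate(zip(counts, primaries))
    ])


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def fisher_oracle(table):
    """Exact-rational Fisher two-sided p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    n, row1, col1 = a + b + c + d, a + b, a + c

    def pmf(k):
        return Fraction(comb(row1, k) * comb(n - row1, col1 - k),
                        comb(n, col1))

    p_obs = pmf(a)
    total = sum(
        pmf(k)
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if pmf(k) <= p_obs
    )
    return float(total)


def mw_oracle(x, y):
    """Brute-force Mann-Whitney: U for x and the exact permutation
    two-sided p over all label assignments (mid-ranks for ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = n * m / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2

    u_obs = u_of(range(n))
    dev = abs(u_obs - mu)
    hits = sum(
        abs(u_of(idx) - mu) >= dev - 1e-12
        for idx in combinations(range(n + m), n)
    )
    return u_obs, hits / comb(n + m, n)


# ---------------------------------------------------------------------------
# Induction scoring
# ---------------------------------------------------------------------------

class TestVulvalIndex:
    def test_all_wild_type_is_three(self):
        assert vulval_index(cohort_from_counts([3.0] * 12)) == 3.0

    def test_mean_of_counts(self):
        assert vulval_index(cohort_from_counts([3, 3, 4, 2])) == 3.0

    def test_half_counts_supported(self):
        assert vulval_index(cohort_from_counts([3.5])) == 3.5

    def test_pooling_is_animal_weighted(self):
        a, b = [3, 4, 5], [2, 2]
        pooled = vulval_index(cohort_from_counts(a + b))
        weighted = (vulval_index(cohort_from_counts(a)) * 3
                    + vulval_index(cohort_from_counts(b)) * 2) / 5
        assert pooled == pytest.approx(weighted)

    def test_empty_rejected(self):
        with pytest.raises(VulquantError):
            vulval_index(InductionCohort([]))

    @pytest.mark.parametrize("count,expected", [
        (4, "hyperinduced"), (3.5, "hyperinduced"),
        (3, "wild-type"),
        (2.5, "hypo-induced"), (0, "hypo-induced"),
    ])
    def test_classification(self, count, expected):
        assert classify_induction(count) == expected


class TestFateShiftTable:
    def test_no_shift(self):
        table = fate_shift_table(
            cohort_from_counts([3] * 5, ["P6.p"] * 5))
        assert table["percent_shifted"] == 0.0

    def test_one_of_twenty(self):
        primaries = ["P6.p"] * 19 + ["P5.p"]
        table = fate_shift_table(cohort_from_counts([3] * 20, primaries))
        assert table["percent_shifted"] == pytest.approx(5.0)
        assert table["P5.p"] == 1

    def test_bad_label_rejected(self):
        with pytest.raises(VulquantError):
            fate_shift_table(cohort_from_counts([3], ["P4.p"]))

    def test_empty_rejected(self):
        with pytest.raises(VulquantError):
            fate_shift_table(InductionCohort([]))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

class TestBootstrapMean:
    def test_constant_input(self):
        res = bootstrap_mean([4.0] * 7, seed=0)
        assert res.point_estimate == 4.0
        assert res.sem == 0.0
        assert res.ci95 == (4.0, 4.0)

    def test_zero_one_matches_enumeration(self):
        # all 4 resamples of {0,1}: means {0, .5, .5, 1}, SD = sqrt(0.125)
        res = bootstrap_mean([0.0, 1.0], n_resamples=10_000, seed=1)
        assert res.sem == pytest.approx(np.sqrt(0.125), abs=0.01)

    def test_sem_near_analytic(self, rng):
        values = rng.normal(10.0, 2.0, size=50)
        res = bootstrap_mean(values, n_resamples=10_000, seed=2)
        analytic = values.std(ddof=1) / np.sqrt(values.size)
        assert res.sem == pytest.approx(analytic, rel=0.15)

    def test_deterministic_under_seed(self):
        a = bootstrap_mean([1, 2, 3, 4.0], seed=5)
        b = bootstrap_mean([1, 2, 3, 4.0], seed=5)
        assert a == b

    def test_error_shrinks_with_resamples(self):
        target = np.sqrt(0.125)
        errs = [
            np.mean([
                abs(bootstrap_mean([0.0, 1.0], n_resamples=n, seed=s).sem
                    - target)
                for s in range(20)
            ])
            for n in (50, 500, 5000)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_normal_ci_option(self):
        res = bootstrap_mean([1, 2, 3, 4.0], seed=0, ci_method="normal")
        lo, hi = res.ci95
        assert lo == pytest.approx(res.point_estimate - 1.96 * res.sem)
        assert hi == pytest.approx(res.point_estimate + 1.96 * res.sem)

    def test_percentile_ci_brackets_estimate(self, rng):
        values = rng.normal(size=30)
        res = bootstrap_mean(values, seed=3)
        assert res.ci95[0] <= res.point_estimate <= res.ci95[1]

    def test_empty_rejected(self):
        with pytest.raises(VulquantError):
            bootstrap_mean([])


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestTTests:
    def test_identical_samples(self):
        t, p = welch_t([1, 2, 3.0], [1, 2, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        _, p = welch_t([1, 2, 3.0], [101, 102, 103.0])
        assert p < 0.01

    def test_welch_matches_hand_formula(self):
        x = np.array([4.1, 5.0, 6.2, 5.5])
        y = np.array([3.0, 3.4, 2.8, 3.9, 3.3])
        t, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (
            vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_student_pools_variance(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0]
        t, p = student_t(x, y)
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
        assert (t, p) == (pytest.approx(t_ref), pytest.approx(p_ref))

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            welch_t([2.0, 2.0], [3.0, 3.0])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_textbook_case(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n, m = rng.integers(2, 6), rng.integers(2, 6)
            x = rng.integers(0, 6, size=n).astype(float)  # frequent ties
            y = rng.integers(0, 6, size=m).astype(float)
            u, p = mann_whitney_u(x, y)
            u_ref, p_ref = mw_oracle(x, y)
            assert u == u_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_asymptotic_close_to_enumeration(self, rng):
        # force the large-sample branch at n = m = 7 and compare with the
        # exact enumeration oracle; the tie-corrected normal approximation
        # with continuity correction is good to ~0.02 at this size
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.normal(size=7)
            y = r.normal(0.5, size=7)
            _, p = mann_whitney_u(x, y)
            _, p_ref = mw_oracle(x, y)
            assert p == pytest.approx(p_ref, abs=0.02)


# ---------------------------------------------------------------------------
# F-test and Fisher
# ---------------------------------------------------------------------------

class TestFTest:
    def test_same_multiset_gives_one(self):
        f, p = f_test_variance([1, 2, 3, 4.0], [4, 3, 2, 1.0])
        assert f == 1.0
        assert p == pytest.approx(1.0)

    def test_variance_ratio_100_significant(self, rng):
        x = rng.normal(0, 10, size=20)
        y = rng.normal(0, 1, size=20)
        _, p = f_test_variance(x, y)
        assert p < 0.001

    def test_matches_direct_cdf(self):
        x = np.array([1.0, 2.5, 3.5, 2.0, 4.0])
        y = np.array([2.0, 2.2, 2.1, 1.9])
        f, p = f_test_variance(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        f_ref = max(vx, vy) / min(vx, vy)
        p_ref = 2 * sps.f.sf(f_ref, 4, 3)
        assert f == pytest.approx(f_ref)
        assert p == pytest.approx(min(1.0, p_ref))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            f_test_variance([1.0, 1.0, 1.0], [1, 2, 3.0])


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation(self):
        p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(fisher_oracle([[10, 0], [0, 10]]))
        assert p < 1e-4

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(60):
            a, b, c, d = rng.integers(0, 16, size=4)
            table = [[int(a), int(b)], [int(c), int(d)]]
            margins = (a + b, c + d, a + c, b + d)
            if min(margins) == 0:
                continue
            assert fisher_exact(table) == pytest.approx(
                fisher_oracle(table), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(VulquantError):
            fisher_exact([[0, 0], [3, 4]])

    def test_noninteger_rejected(self):
        with pytest.raises(VulquantError):
            fisher_exact(np.array([[1.5, 2.0], [3.0, 4.0]]))


# ---------------------------------------------------------------------------
# Type-I error calibration (reduced replicate count; the acceptance suite
# runs the full 2,000-replicate version)
# ---------------------------------------------------------------------------

class TestTypeIError:
    def test_null_rejection_rates(self):
        n_rep, alpha = 400, 0.05
        rej_t = rej_u = 0
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=30), r.normal(size=30)
            rej_t += welch_t(x, y)[1] < alpha
            rej_u += mann_whitney_u(x, y)[1] < alpha
        for rej in (rej_t, rej_u):
            # 3 binomial SDs around alpha at 400 replicates
            assert abs(rej / n_rep - alpha) <= 3 * np.sqrt(
                alpha * (1 - alpha) / n_rep)
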