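"""Imbalance statistics: closed-form values, oracle equivalence against
scipy's reference tests, and the vote-direction guarantee."""

import math

import numpy as np
import pytest
from scipy import stats

from msbalance import (
    CovariateKind,
    CovariateSpec,
    InsufficientDataError,
    MSBConfig,
    StateError,
    Vote,
    covariate_vote,
    imbalance_test,
    risk_difference,
    std_diff_binary,
    std_diff_continuous,
)
from msbalance.balance import exact_binomial_p, proportions_p_value, welch_p_value

from conftest import make_binary_state, make_continuous_state, new_unit


class TestStdDiffContinuous:
    def test_identical_groups_give_zero(self):
        assert std_diff_continuous([1, 2, 3], [1, 2, 3]) == 0.0

    def test_antisymmetry(self):
        d = std_diff_continuous([1, 2, 3, 4], [2, 3, 4, 5])
        assert std_diff_continuous([2, 3, 4, 5], [1, 2, 3, 4]) == pytest.approx(-d)

    def test_pooled_sd_regression_value(self):
        # hand evaluation: means 2.5 vs 3.5, pooled SD sqrt(5/3)
        assert std_diff_continuous([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(
            -0.7745966692414834
        )

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            std_diff_continuous([1], [1, 2])

    def test_zero_spread_unequal_means_is_signed_infinity(self):
        assert std_diff_continuous([3, 3], [1, 1]) == math.inf
        assert std_diff_continuous([1, 1], [3, 3]) == -math.inf


class TestStdDiffBinary:
    def test_equal_proportions_give_zero(self):
        assert std_diff_binary(5, 10, 5, 10) == 0.0

    def test_closed_form_value(self):
        # p0=0.8, p1=0.2 -> 0.6 / sqrt(0.16) = 1.5
        assert std_diff_binary(8, 10, 2, 10) == pytest.approx(1.5)

    def test_antisymmetry(self):
        assert std_diff_binary(2, 10, 8, 10) == pytest.approx(-1.5)

    def test_degenerate_denominator(self):
        assert std_diff_binary(0, 5, 0, 7) == 0.0
        assert std_diff_binary(5, 5, 0, 7) == math.inf

    def test_count_domain_error(self):
        with pytest.raises(ValueError):
            std_diff_binary(11, 10, 2, 10)


class TestRiskDifference:
    @pytest.mark.parametrize(
        "args,expected",
        [((5, 10, 5, 10), 0.0), ((6, 10, 4, 10), 0.2), ((0, 10, 10, 10), -1.0)],
    )
    def test_values(self, args, expected):
        assert risk_difference(*args) == pytest.approx(expected)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            risk_difference(0, 0, 1, 2)


class TestImbalanceTest:
    def test_identical_multisets_are_balanced(self):
        state = make_continuous_state([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        r = imbalance_test(state, state.specs[0], 6)
        assert r.p_value == pytest.approx(1.0)
        assert r.std_diff == 0.0

    def test_strong_binary_imbalance_is_overwhelming(self):
        state = make_binary_state(80, 100, 20, 100)
        r = imbalance_test(state, state.specs[0], 200, level="yes")
        assert r.p_value < 1e-15
        assert r.std_diff == pytest.approx(std_diff_binary(80, 100, 20, 100))
        assert r.risk_diff == pytest.approx(0.6)

    def test_empty_arm_degenerates_to_p_one(self):
        spec = CovariateSpec("trait", CovariateKind.BINARY, ("no", "yes"))
        from msbalance import TrialState, UnitRecord, AllocationSource

        state = TrialState(("A", "B"), [spec], MSBConfig())
        u = UnitRecord("u0", ready=True, covariates={"trait": "yes"})
        state.add_unit(u)
        state.record_allocation("u0", "A", 0.5, [], AllocationSource.ALGORITHM)
        r = imbalance_test(state, spec, 1, level="yes")
        assert r.p_value == 1.0
        assert r.statistic is None

    def test_inactive_covariate_is_a_precondition_error(self):
        state = make_continuous_state([1.0, 2.0], [3.0, 4.0])
        from dataclasses import replace

        late = replace(state.specs[0], active_from=100)
        with pytest.raises(StateError):
            imbalance_test(state, late, 4)

    def test_fisher_used_for_small_expected_cells(self):
        state = make_binary_state(2, 6, 0, 6)
        r = imbalance_test(state, state.specs[0], 12, level="yes")
        assert r.test == "fisher"
        _, p = stats.fisher_exact([[2, 4], [0, 6]])
        assert r.p_value == pytest.approx(p)


class TestOracleEquivalence:
    """Closed-form p-values agree with the scipy reference
    implementations to 1e-8 over 1,000 random small instances."""

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(101)
        for _ in range(1000):
            n0, n1 = rng.integers(2, 30, size=2)
            x = rng.normal(0, 1, n0)
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n1)
            t, p = welch_p_value(
                x.mean(), x.var(ddof=1), n0, y.mean(), y.var(ddof=1), n1
            )
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)
            assert t == pytest.approx(ref.statistic, abs=1e-8)

    def test_proportions_match_scipy(self):
        rng = np.random.default_rng(202)
        checked_chi2 = checked_fisher = 0
        for _ in range(1000):
            n0, n1 = rng.integers(1, 60, size=2)
            k0 = int(rng.integers(0, n0 + 1))
            k1 = int(rng.integers(0, n1 + 1))
            table = [[k0, n0 - k0], [k1, n1 - k1]]
            stat, p, test = proportions_p_value(k0, n0, k1, n1)
            if test == "chi2":
                ref = stats.chi2_contingency(table, correction=False)
                assert p == pytest.approx(ref.pvalue, abs=1e-8)
                checked_chi2 += 1
            else:
                _, ref_p = stats.fisher_exact(table)
                assert p == pytest.approx(ref_p, abs=1e-8)
                checked_fisher += 1
        assert checked_chi2 > 100 and checked_fisher > 100

    def test_exact_binomial_matches_scipy(self):
        rng = np.random.default_rng(303)
        for _ in range(300):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            ref = stats.binomtest(k, n, 0.5).pvalue
            assert exact_binomial_p(k, n) == pytest.approx(ref, abs=1e-8)


def _abs_d_binary_after(k0, n0, k1, n1, arm_index, positive):
    k = [k0, k1]
    n = [n0, n1]
    n[arm_index] += 1
    if positive:
        k[arm_index] += 1
    return abs(std_diff_binary(k[0], n[0], k[1], n[1]))


def _abs_d_cont_after(v0, v1, arm_index, x):
    v0, v1 = list(v0), list(v1)
    (v0 if arm_index == 0 else v1).append(x)
    return abs(std_diff_continuous(v0, v1))


class TestCovariateVote:
    def test_no_vote_without_significance(self):
        state = make_binary_state(12, 20, 10, 20)
        spec = state.specs[0]
        r = imbalance_test(state, spec, 40, level="yes")
        r.p_value = 0.9  # force an insignificant report
        assert covariate_vote(r, spec, new_unit("x", trait="yes"), state) is Vote.NONE

    def test_no_vote_when_value_missing(self):
        state = make_binary_state(80, 100, 20, 100)
        spec = state.specs[0]
        r = imbalance_test(state, spec, 200, level="yes")
        assert covariate_vote(r, spec, new_unit("x"), state) is Vote.NONE

    def test_binary_trait_positive_unit_goes_to_low_prevalence_arm(self):
        state = make_binary_state(80, 100, 20, 100)
        spec = state.specs[0]
        r = imbalance_test(state, spec, 200, level="yes")
        vote = covariate_vote(r, spec, new_unit("x", trait="yes"), state)
        assert vote is Vote.ARM1
        # assigning there shrinks the imbalance relative to the other arm
        assert _abs_d_binary_after(80, 100, 20, 100, 1, True) <= _abs_d_binary_after(
            80, 100, 20, 100, 0, True
        )

    def test_binary_trait_negative_unit_goes_to_high_prevalence_arm(self):
        state = make_binary_state(80, 100, 20, 100)
        spec = state.specs[0]
        r = imbalance_test(state, spec, 200, level="yes")
        assert covariate_vote(r, spec, new_unit("x", trait="no"), state) is Vote.ARM0

    def test_continuous_high_value_goes_to_low_mean_arm(self):
        rng = np.random.default_rng(5)
        v0 = list(rng.normal(0.0, 1.0, 40))
        v1 = list(rng.normal(1.5, 1.0, 40))
        state = make_continuous_state(v0, v1)
        spec = state.specs[0]
        r = imbalance_test(state, spec, 80)
        assert r.p_value < 0.3
        x = 3.0  # above the pooled mean
        vote = covariate_vote(r, spec, new_unit("x", age=x), state)
        assert vote is Vote.ARM0  # arm 0 has the smaller mean
        assert _abs_d_cont_after(v0, v1, 0, x) <= _abs_d_cont_after(v0, v1, 1, x)

    def test_tie_on_pooled_mean_casts_no_vote(self):
        state = make_continuous_state([0.0, 1.0, 2.0], [3.0, 4.0, 5.0])
        spec = state.specs[0]
        r = imbalance_test(state, spec, 6)
        pooled = 2.5
        assert covariate_vote(r, spec, new_unit("x", age=pooled), state) is Vote.NONE

    def test_antisymmetry_under_arm_swap(self):
        cfg = MSBConfig(size_balance=False)
        s1 = make_binary_state(70, 90, 25, 80, config=cfg)
        s2 = make_binary_state(25, 80, 70, 90, config=cfg)
        r1 = imbalance_test(s1, s1.specs[0], 170, level="yes")
        r2 = imbalance_test(s2, s2.specs[0], 170, level="yes")
        assert r1.std_diff == pytest.approx(-r2.std_diff)
        assert r1.risk_diff == pytest.approx(-r2.risk_diff)
        assert r1.p_value == pytest.approx(r2.p_value)
        u = new_unit("x", trait="yes")
        v1 = covariate_vote(r1, s1.specs[0], u, s1)
        v2 = covariate_vote(r2, s2.specs[0], u, s2)
        assert {v1, v2} == {Vote.ARM0, Vote.ARM1}


class TestVoteDirectionProperty:
    """Whenever a vote is cast, hypothetically assigning the unit to the
    voted arm never leaves a larger |d| than the alternative arm would —
    checked over >= 1,000 random instances per covariate kind."""

    def test_binary(self):
        rng = np.random.default_rng(42)
        votes_seen = 0
        while votes_seen < 1000:
            n0, n1 = rng.integers(5, 60, size=2)
            k0 = int(rng.binomial(n0, rng.uniform(0.1, 0.9)))
            k1 = int(rng.binomial(n1, rng.uniform(0.1, 0.9)))
            state = make_binary_state(k0, int(n0), k1, int(n1))
            spec = state.specs[0]
            positive = bool(rng.random() < 0.5)
            unit = new_unit("x", trait="yes" if positive else "no")
            r = imbalance_test(state, spec, int(n0 + n1), level="yes" if positive else "no")
            vote = covariate_vote(r, spec, unit, state)
            if vote is Vote.NONE:
                continue
            votes_seen += 1
            voted = 0 if vote is Vote.ARM0 else 1
            d_voted = _abs_d_binary_after(k0, n0, k1, n1, voted, positive)
            d_other = _abs_d_binary_after(k0, n0, k1, n1, 1 - voted, positive)
            assert d_voted <= d_other + 1e-12, (k0, n0, k1, n1, positive, vote)

    def test_continuous(self):
        rng = np.random.default_rng(43)
        votes_seen = 0
        while votes_seen < 1000:
            n0, n1 = rng.integers(5, 40, size=2)
            v0 = rng.normal(0.0, 1.0, n0)
            v1 = rng.normal(rng.uniform(-1.5, 1.5), 1.0, n1)
            state = make_continuous_state(v0, v1)
            spec = state.specs[0]
            x = float(rng.normal(0.0, 2.0))
            unit = new_unit("x", age=x)
            r = imbalance_test(state, spec, int(n0 + n1))
            vote = covariate_vote(r, spec, unit, state)
            if vote is Vote.NONE:
                continue
            votes_seen += 1
            voted = 0 if vote is Vote.ARM0 else 1
            d_voted = _abs_d_cont_after(v0, v1, voted, x)
            d_other = _abs_d_cont_after(v0, v1, 1 - voted, x)
            assert d_voted <= d_other + 1e-12
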