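"""Per-covariate imbalance statistics, tests and arm votes.

For every balancing covariate the engine asks three questions about the
already-randomized units: how imbalanced are the arms (standardized
difference, and risk difference for non-continuous covariates), is the
imbalance statistically notable (p-value below the vote threshold eta),
and if so, which arm should the incoming unit join to shrink it (the
vote).

Test families
-------------
continuous   Welch two-sample t-test (unequal variances).
binary /     chi-square test of proportions on the 2x2 table of the
categorical  indicator level, switching to Fisher's exact test whenever
             any expected cell count is below 5. Categorical covariates
             are tested one-vs-rest at the incoming unit's own level:
             a vote needs a direction, which an omnibus test lacks.

P-values are computed from the closed-form test statistics and the
scipy.stats distribution functions so each test runs in O(1) from the
trial state's incremental per-arm aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .model import (
    CovariateKind,
    CovariateSpec,
    StateError,
    TrialState,
    UnitRecord,
)

__all__ = [
    "Vote",
    "BalanceReport",
    "InsufficientDataError",
    "std_diff_continuous",
    "std_diff_binary",
    "risk_difference",
    "imbalance_test",
    "covariate_vote",
    "balance_table",
]


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class Vote(str, Enum):
    ARM0 = "arm0"
    ARM1 = "arm1"
    NONE = "none"


@dataclass
class BalanceReport:
    """Result of one covariate's imbalance assessment.

    ``std_diff`` and ``risk_diff`` are signed arm0-minus-arm1; ``level``
    is the indicator level tested for binary/categorical covariates;
    ``test`` names the test actually used ("welch_t", "chi2", "fisher",
    or "none" for degenerate data).
    """

    covariate: str
    n_by_arm: tuple
    statistic: Optional[float]
    p_value: float
    std_diff: float
    risk_diff: Optional[float] = None
    vote: Vote = Vote.NONE
    level: Optional[str] = None
    test: str = "none"


def std_diff_continuous(values_arm0: Sequence[float], values_arm1: Sequence[float]) -> float:
    """Standardized mean difference d = (mean0 - mean1) / s_pooled.

    ``s_pooled`` is the usual pooled standard deviation
    sqrt(((n0-1)s0^2 + (n1-1)s1^2) / (n0+n1-2)). Returns 0 when both
    variances vanish and the means agree; signed infinity when the
    pooled SD is 0 but the means differ.
    """
    x0 = [float(v) for v in values_arm0]
    x1 = [float(v) for v in values_arm1]
    if len(x0) < 2 or len(x1) < 2:
        raise InsufficientDataError("each arm needs >= 2 values for a standardized difference")
    n0, n1 = len(x0), len(x1)
    m0, m1 = sum(x0) / n0, sum(x1) / n1
    v0 = sum((v - m0) ** 2 for v in x0) / (n0 - 1)
    v1 = sum((v - m1) ** 2 for v in x1) / (n1 - 1)
    return _std_diff_from_moments(m0, v0, n0, m1, v1, n1)


def _std_diff_from_moments(m0, v0, n0, m1, v1, n1) -> float:
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    if sp2 <= 0.0:
        if m0 == m1:
            return 0.0
        return math.copysign(math.inf, m0 - m1)
    return (m0 - m1) / math.sqrt(sp2)


def std_diff_binary(k0: int, n0: int, k1: int, n1: int) -> float:
    """Standardized difference of two proportions:
    (p0 - p1) / sqrt((p0(1-p0) + p1(1-p1)) / 2).
    """
    _check_counts(k0, n0, k1, n1)
    p0, p1 = k0 / n0, k1 / n1
    denom2 = (p0 * (1 - p0) + p1 * (1 - p1)) / 2
    if denom2 <= 0.0:
        if p0 == p1:
            return 0.0
        return math.copysign(math.inf, p0 - p1)
    return (p0 - p1) / math.sqrt(denom2)


def risk_difference(k0: int, n0: int, k1: int, n1: int) -> float:
    """Difference in proportions p0 - p1."""
    _check_counts(k0, n0, k1, n1)
    return k0 / n0 - k1 / n1


def _check_counts(k0, n0, k1, n1) -> None:
    if n0 < 1 or n1 < 1:
        raise ValueError("arm sizes must be >= 1")
    if not (0 <= k0 <= n0 and 0 <= k1 <= n1):
        raise ValueError("event counts must satisfy 0 <= k <= n")


def welch_p_value(m0, v0, n0, m1, v1, n1) -> tuple:
    """Welch two-sample t statistic and two-sided p-value from moments."""
    se0, se1 = v0 / n0, v1 / n1
    se2 = se0 + se1
    if se2 <= 0.0:
        if m0 == m1:
            return 0.0, 1.0
        return math.copysign(math.inf, m0 - m1), 0.0
    t = (m0 - m1) / math.sqrt(se2)
    df = se2 * se2 / (se0 * se0 / (n0 - 1) + se1 * se1 / (n1 - 1))
    return t, 2.0 * float(stats.t.sf(abs(t), df))


def proportions_p_value(k0: int, n0: int, k1: int, n1: int) -> tuple:
    """Chi-square test of two proportions without continuity correction,
    falling back to Fisher's exact test when any expected cell < 5.

    Returns (statistic, p_value, test_name); the statistic is the
    chi-square value, or the sample odds ratio under the Fisher path.
    """
    a, b = k0, n0 - k0
    c, d = k1, n1 - k1
    n = n0 + n1
    col0, col1 = a + c, b + d
    expected_min = min(
        n0 * col0, n0 * col1, n1 * col0, n1 * col1
    ) / n
    if expected_min < 5:
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        return float(odds), float(p), "fisher"
    num = n * (a * d - b * c) ** 2
    den = n0 * n1 * col0 * col1
    chi2 = num / den
    return float(chi2), float(stats.chi2.sf(chi2, 1)), "chi2"


def exact_binomial_p(k: int, n: int) -> float:
    """Two-sided exact binomial p-value at rate 1/2 (symmetric case:
    twice the smaller tail, capped at 1)."""
    if n == 0:
        return 1.0
    lo = float(stats.binom.cdf(k, n, 0.5))
    hi = float(stats.binom.sf(k - 1, n, 0.5))
    return min(1.0, 2.0 * min(lo, hi))


def imbalance_test(
    state: TrialState,
    spec: CovariateSpec,
    at_index: int,
    level: Optional[str] = None,
) -> BalanceReport:
    """Test the current between-arm imbalance of one covariate.

    ``at_index`` is the enrollment index of the incoming unit (i.e. the
    number of units already randomized); the covariate must be active
    there. ``level`` selects the indicator level for binary/categorical
    covariates — normally the incoming unit's own level. Binary
    covariates default to their last declared level; categorical
    covariates require an explicit level.

    When either arm lacks enough non-missing data the report degenerates
    to p_value = 1 with no statistic, so the covariate cannot vote.
    """
    if not spec.is_active(at_index):
        raise StateError(
            f"covariate {spec.name!r} is inactive before enrollment index {spec.active_from}"
        )
    agg = state.aggregate(spec.name)
    n0, n1 = agg.n

    if spec.kind is CovariateKind.CONTINUOUS:
        if n0 < 2 or n1 < 2:
            return BalanceReport(spec.name, (n0, n1), None, 1.0, 0.0)
        m0, m1 = agg.mean(0), agg.mean(1)
        v0, v1 = agg.var(0), agg.var(1)
        t, p = welch_p_value(m0, v0, n0, m1, v1, n1)
        d = _std_diff_from_moments(m0, v0, n0, m1, v1, n1)
        return BalanceReport(spec.name, (n0, n1), t, p, d, test="welch_t")

    if level is None:
        if spec.kind is CovariateKind.BINARY:
            level = spec.levels[-1]
        else:
            raise ValueError(
                f"categorical covariate {spec.name!r} needs an indicator level"
            )
    elif level not in spec.levels:
        raise ValueError(f"covariate {spec.name!r}: unknown level {level!r}")
    if n0 < 1 or n1 < 1:
        return BalanceReport(spec.name, (n0, n1), None, 1.0, 0.0, risk_diff=0.0, level=level)
    k0 = agg.level_count(0, level)
    k1 = agg.level_count(1, level)
    statistic, p, test = proportions_p_value(k0, n0, k1, n1)
    return BalanceReport(
        spec.name,
        (n0, n1),
        statistic,
        p,
        std_diff_binary(k0, n0, k1, n1),
        risk_diff=risk_difference(k0, n0, k1, n1),
        level=level,
        test=test,
    )


def _hypothetical_d_continuous(agg, x: float, arm_index: int) -> float:
    """Standardized difference after hypothetically adding value ``x``
    to one arm, from the running (n, sum, sum-of-squares) aggregates."""
    n = list(agg.n)
    s = list(agg.s)
    ss = list(agg.ss)
    n[arm_index] += 1
    s[arm_index] += x
    ss[arm_index] += x * x
    means, variances = [], []
    for i in (0, 1):
        m = s[i] / n[i]
        means.append(m)
        variances.append(max((ss[i] - n[i] * m * m) / (n[i] - 1), 0.0))
    return _std_diff_from_moments(
        means[0], variances[0], n[0], means[1], variances[1], n[1]
    )


def covariate_vote(
    report: BalanceReport,
    spec: CovariateSpec,
    new_unit: UnitRecord,
    state: TrialState,
) -> Vote:
    """Which arm should the incoming unit join to reduce this covariate's
    imbalance?

    No vote when the test is not significant at eta, the unit's value is
    missing, or there is no direction (value exactly at the pooled mean;
    equal proportions). Continuous: the vote goes to the arm whose
    hypothetical post-assignment |standardized difference| is smaller,
    evaluated exactly from the running moments — for values clearly
    outside the two arm means this coincides with the classical
    send-high-values-to-the-low-mean-arm rule, and unlike that shortcut
    it also picks the imbalance-minimizing arm when the value falls
    between the pooled mean and the farther arm mean. Binary/
    categorical: a unit carrying the indicator trait goes to the arm
    where the trait is rarer, a unit without it to the arm where the
    trait is more common.
    """
    eta = state.config.p_threshold
    if report.p_value >= eta:
        return Vote.NONE
    value = new_unit.value(spec.name)
    if value is None:
        return Vote.NONE
    agg = state.aggregate(spec.name)

    if spec.kind is CovariateKind.CONTINUOUS:
        n0, n1 = agg.n
        if n0 < 2 or n1 < 2:
            return Vote.NONE
        x = float(value)
        pooled_mean = (agg.s[0] + agg.s[1]) / (n0 + n1)
        if agg.mean(0) == agg.mean(1) or x == pooled_mean:
            return Vote.NONE
        d0 = abs(_hypothetical_d_continuous(agg, x, 0))
        d1 = abs(_hypothetical_d_continuous(agg, x, 1))
        if d0 == d1:
            return Vote.NONE
        return Vote.ARM0 if d0 < d1 else Vote.ARM1

    level = report.level
    n0, n1 = agg.n
    if level is None or n0 < 1 or n1 < 1:
        return Vote.NONE
    p0 = agg.level_count(0, level) / n0
    p1 = agg.level_count(1, level) / n1
    if p0 == p1:
        return Vote.NONE
    has_trait = str(value) == level
    if has_trait:
        return Vote.ARM0 if p0 < p1 else Vote.ARM1
    return Vote.ARM0 if p0 > p1 else Vote.ARM1


def balance_table(reports: Sequence[BalanceReport]) -> pd.DataFrame:
    """Tabulate balance reports, one row per covariate (the Table-1-style
    export: statistic, p-value, standardized and risk differences, vote)."""
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate,
                "n_arm0": r.n_by_arm[0],
                "n_arm1": r.n_by_arm[1],
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "std_diff": r.std_diff,
                "risk_diff": r.risk_diff,
                "vote": r.vote.value,
            }
            for r in reports
        ]
    )
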