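"""Minimal sufficient balance (MSB) allocation engine.

MSB biases the randomization coin only when pre-specified per-covariate
imbalance criteria trigger; otherwise it randomizes 1:1, preserving
allocation randomness. For each incoming unit past the burn-in, every
active covariate is tested for between-arm imbalance and, if significant
at the vote threshold eta, casts a vote for the arm the unit should join
to shrink that imbalance. An optional arm-size criterion (exact binomial
test, recorded as "sample_size") votes alongside the covariates. A
strict majority of votes earns that arm the biased-coin probability
p_b > 0.5; ties or no votes fall back to a fair coin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import balance
from .balance import Vote
from .model import (
    AllocationSource,
    MSBConfig,
    StateError,
    TrialState,
    UnitRecord,
    validate_unit,
)

__all__ = [
    "AllocationResult",
    "AllocationRejected",
    "size_vote",
    "decide_probability",
    "propose_allocation",
    "commit_allocation",
    "randomize_unit",
]


class AllocationRejected(StateError):
    """Unit failed covariate validation; carries the issue list."""

    def __init__(self, unit_id: str, issues: List[str]) -> None:
        super().__init__(f"unit {unit_id!r} rejected: " + "; ".join(issues))
        self.unit_id = unit_id
        self.issues = list(issues)


@dataclass
class AllocationResult:
    """Outcome of one randomization: the assigned arm, the biased-coin
    probability given to the favored arm (0.5 when no bias applied), the
    vote tally, the balance criteria that informed the bias, and the
    uniform draw consumed — enough to replay and audit the allocation.
    """

    unit_id: str
    arm: str
    probability_used: float
    favored_arm: Optional[str]
    votes_arm0: int
    votes_arm1: int
    criteria: List[str] = field(default_factory=list)
    rng_draw: float = 0.0
    source: AllocationSource = AllocationSource.ALGORITHM

    @property
    def arm_probability(self) -> float:
        """Probability with which the *assigned* arm was drawn."""
        if self.favored_arm is None:
            return 0.5
        if self.arm == self.favored_arm:
            return self.probability_used
        return 1.0 - self.probability_used

    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "arm": self.arm,
            "probability_used": self.probability_used,
            "arm_probability": self.arm_probability,
            "favored_arm": self.favored_arm,
            "votes_arm0": self.votes_arm0,
            "votes_arm1": self.votes_arm1,
            "criteria": list(self.criteria),
            "rng_draw": self.rng_draw,
            "source": self.source.value,
        }


def size_vote(state: TrialState, config: MSBConfig) -> Vote:
    """Arm-size criterion: a two-sided exact binomial test of the current
    arm-0 count against a fair 1:1 split; a significant result votes for
    the smaller arm."""
    if not config.size_balance:
        return Vote.NONE
    n0, n1 = state.arm_sizes()
    if n0 == n1:
        return Vote.NONE
    p = balance.exact_binomial_p(n0, n0 + n1)
    if p >= config.p_threshold:
        return Vote.NONE
    return Vote.ARM0 if n0 < n1 else Vote.ARM1


def decide_probability(votes_arm0: int, votes_arm1: int, config: MSBConfig) -> tuple:
    """Map the vote tally to (favored_vote, probability): a strict
    majority earns p_b for that arm, otherwise a fair coin."""
    if votes_arm0 > votes_arm1:
        return Vote.ARM0, config.biased_probability
    if votes_arm1 > votes_arm0:
        return Vote.ARM1, config.biased_probability
    return Vote.NONE, 0.5


def propose_allocation(
    state: TrialState, unit: UnitRecord, rng: np.random.Generator
) -> AllocationResult:
    """Run MSB for one unit and draw its arm, without mutating the state.

    During the burn-in (fewer than ``config.burn_in`` units randomized)
    the draw is simple 1:1 with no criteria consulted. Afterwards every
    covariate active at the unit's enrollment index is tested and voted;
    ``criteria`` lists the names that voted for the favored arm (empty
    when no bias was applied). Exactly one uniform variate is consumed
    per call, so a fixed seed replays the whole allocation sequence.
    """
    if not unit.ready:
        raise StateError(f"unit {unit.unit_id!r} is not ready to be randomized")
    if unit.is_randomized:
        raise StateError(f"unit {unit.unit_id!r} is already randomized")
    issues = validate_unit(state, unit)
    if issues:
        raise AllocationRejected(unit.unit_id, issues)

    config = state.config
    at_index = state.n_randomized
    votes = {}
    if at_index >= config.burn_in:
        for spec in state.specs:
            if not spec.is_active(at_index):
                continue
            value = unit.value(spec.name)
            if value is None:
                continue  # a unit missing the covariate casts no vote for it
            level = None if spec.kind.value == "continuous" else str(value)
            report = balance.imbalance_test(state, spec, at_index, level=level)
            v = balance.covariate_vote(report, spec, unit, state)
            if v is not Vote.NONE:
                votes[spec.name] = v
        sv = size_vote(state, config)
        if sv is not Vote.NONE:
            votes["sample_size"] = sv

    v0 = sum(1 for v in votes.values() if v is Vote.ARM0)
    v1 = sum(1 for v in votes.values() if v is Vote.ARM1)
    favored, prob = decide_probability(v0, v1, config)

    draw = float(rng.random())
    if favored is Vote.ARM0:
        p_arm0 = prob
    elif favored is Vote.ARM1:
        p_arm0 = 1.0 - prob
    else:
        p_arm0 = 0.5
    arm = state.arms[0] if draw < p_arm0 else state.arms[1]

    favored_label = None
    criteria: List[str] = []
    if favored is not Vote.NONE:
        favored_label = state.arms[0] if favored is Vote.ARM0 else state.arms[1]
        criteria = [name for name, v in votes.items() if v is favored]
    return AllocationResult(
        unit_id=unit.unit_id,
        arm=arm,
        probability_used=prob,
        favored_arm=favored_label,
        votes_arm0=v0,
        votes_arm1=v1,
        criteria=criteria,
        rng_draw=draw,
    )


def commit_allocation(state: TrialState, result: AllocationResult) -> UnitRecord:
    """Record a proposed allocation in the trial state."""
    return state.record_allocation(
        result.unit_id,
        result.arm,
        result.arm_probability,
        result.criteria,
        result.source,
    )


def randomize_unit(
    state: TrialState, unit: UnitRecord, rng: np.random.Generator
) -> AllocationResult:
    """Allocate one ready, validated, not-yet-randomized unit and commit
    the result (arm, arm probability, criteria, enrollment index) to the
    trial state."""
    result = propose_allocation(state, unit, rng)
    commit_allocation(state, result)
    return result
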