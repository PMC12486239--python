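"""Domain model for a 2-arm covariate-adaptive trial.

Defines the balancing-covariate specifications, the unit of randomization
(a single participant or a partnered dyad randomized together), the
algorithm configuration, and the mutable trial state that the allocation
engine operates on.

Sign convention used throughout the package: the first listed arm is
"arm 0", and a positive standardized or risk difference means arm 0's
mean/proportion is the larger one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "CovariateKind",
    "AllocationSource",
    "CovariateSpec",
    "UnitRecord",
    "MSBConfig",
    "TrialState",
    "ConfigError",
    "StateError",
    "load_config",
    "validate_unit",
]

CovariateValue = Union[float, str]


class ConfigError(ValueError):
    """Raised when a run configuration or domain invariant is violated."""


class StateError(RuntimeError):
    """Raised on invalid trial-state transitions (e.g. double allocation)."""


class CovariateKind(str, Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"
    CATEGORICAL = "categorical"


class AllocationSource(str, Enum):
    ALGORITHM = "algorithm"
    BACKUP_LIST = "backup_list"
    UNSET = "unset"


@dataclass(frozen=True)
class CovariateSpec:
    """One balancing covariate.

    Parameters
    ----------
    name : str
        Identifier; also the ``covariate.<name>`` store column.
    kind : CovariateKind
        ``continuous``, ``binary`` or ``categorical``.
    levels : tuple of str
        Ordered level labels; binary specs have exactly 2, categorical
        at least 2, continuous none.
    active_from : int
        Enrollment index at which the covariate starts casting votes.
        0 means active from the first randomization; a positive value
        models a covariate added mid-trial (the trial this package
        emulates added baseline STI test results to its algorithm part
        way through enrollment).
    required : bool
        Whether a missing value blocks randomization of the unit.
    """

    name: str
    kind: CovariateKind
    levels: tuple = ()
    active_from: int = 0
    required: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CovariateKind(self.kind))
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if not self.name:
            raise ConfigError("covariate name must be non-empty")
        if self.active_from < 0:
            raise ConfigError(f"covariate {self.name!r}: active_from must be >= 0")
        if self.kind is CovariateKind.CONTINUOUS:
            if self.levels:
                raise ConfigError(f"covariate {self.name!r}: continuous specs have no levels")
        elif self.kind is CovariateKind.BINARY:
            if len(self.levels) != 2:
                raise ConfigError(f"covariate {self.name!r}: binary specs need exactly 2 levels")
        else:
            if len(self.levels) < 2:
                raise ConfigError(f"covariate {self.name!r}: categorical specs need >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigError(f"covariate {self.name!r}: duplicate levels")

    def is_active(self, enrollment_index: int) -> bool:
        return enrollment_index >= self.active_from


@dataclass
class UnitRecord:
    """One unit of randomization: an individual or a dyad allocated together."""

    unit_id: str
    member_record_ids: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)
    ready: bool = False
    arm: Optional[str] = None
    allocation_probability: Optional[float] = None
    criteria: Optional[list] = None
    source: AllocationSource = AllocationSource.UNSET
    enrollment_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.source = AllocationSource(self.source)
        if not self.unit_id:
            raise ConfigError("unit_id must be non-empty")
        if not self.member_record_ids:
            self.member_record_ids = [self.unit_id]
        if not 1 <= len(self.member_record_ids) <= 2:
            raise ConfigError(f"unit {self.unit_id!r}: units hold 1 or 2 member records")
        if (self.arm is not None) != (self.source is not AllocationSource.UNSET):
            raise ConfigError(f"unit {self.unit_id!r}: arm is set iff source != unset")
        if self.allocation_probability is not None:
            if self.arm is None:
                raise ConfigError(
                    f"unit {self.unit_id!r}: allocation_probability set without an arm"
                )
            if not 0.0 < self.allocation_probability < 1.0:
                raise ConfigError(
                    f"unit {self.unit_id!r}: allocation_probability must lie in (0,1)"
                )

    @property
    def is_randomized(self) -> bool:
        return self.arm is not None

    @property
    def is_dyad(self) -> bool:
        return len(self.member_record_ids) == 2

    def value(self, name: str) -> Optional[CovariateValue]:
        """Covariate value, or None when missing."""
        v = self.covariates.get(name)
        if v is None:
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        return v


@dataclass(frozen=True)
class MSBConfig:
    """Tunable parameters of the minimal-sufficient-balance engine.

    p_threshold : float
        Significance level eta for the per-covariate imbalance tests;
        a covariate only casts a vote when its test p-value < eta.
    biased_probability : float
        Biased-coin probability p_b in (0.5, 1) given to the favored arm
        when a strict majority of triggered criteria points there.
    burn_in : int
        Number of initial units allocated by simple 1:1 randomization
        before the adaptive logic activates.
    size_balance : bool
        Whether arm-size imbalance (exact binomial test) casts a vote,
        recorded under the criterion name ``"sample_size"``.
    seed : int
        Seed of the shared random stream consumed in enrollment order.
    """

    p_threshold: float = 0.3
    biased_probability: float = 0.7
    burn_in: int = 20
    size_balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigError("p_threshold must lie in (0, 1)")
        if not 0.5 < self.biased_probability < 1.0:
            raise ConfigError("biased_probability must lie in (0.5, 1)")
        if self.burn_in < 0:
            raise ConfigError("burn_in must be >= 0")


class _ArmAggregate:
    """Incremental per-arm sufficient statistics for one covariate.

    Continuous: (n, sum, sum of squares) per arm.
    Binary/categorical: per-level counts and non-missing totals per arm.
    Kept in sync by TrialState as allocations are recorded, so every
    per-allocation balance test runs in O(1) regardless of trial size.
    """

    __slots__ = ("kind", "n", "s", "ss", "level_counts")

    def __init__(self, spec: CovariateSpec) -> None:
        self.kind = spec.kind
        self.n = [0, 0]
        self.s = [0.0, 0.0]
        self.ss = [0.0, 0.0]
        self.level_counts = [
            {lvl: 0 for lvl in spec.levels},
            {lvl: 0 for lvl in spec.levels},
        ]

    def add(self, arm_index: int, value: CovariateValue) -> None:
        self.n[arm_index] += 1
        if self.kind is CovariateKind.CONTINUOUS:
            v = float(value)
            self.s[arm_index] += v
            self.ss[arm_index] += v * v
        else:
            self.level_counts[arm_index][str(value)] += 1

    def mean(self, arm_index: int) -> float:
        return self.s[arm_index] / self.n[arm_index]

    def var(self, arm_index: int) -> float:
        """Unbiased sample variance (ddof=1); requires n >= 2."""
        n = self.n[arm_index]
        m = self.mean(arm_index)
        return max((self.ss[arm_index] - n * m * m) / (n - 1), 0.0)

    def level_count(self, arm_index: int, level: str) -> int:
        return self.level_counts[arm_index][level]


class TrialState:
    """Mutable state of a sequential 2-arm trial.

    Holds the arm labels, covariate specifications, engine configuration
    and all unit records, and maintains the enrollment-ordered allocation
    sequence plus incremental balance aggregates.
    """

    def __init__(
        self,
        arms: Sequence[str],
        specs: Sequence[CovariateSpec],
        config: MSBConfig,
        units: Iterable[UnitRecord] = (),
    ) -> None:
        arms = [str(a) for a in arms]
        if len(arms) != 2 or arms[0] == arms[1]:
            raise ConfigError("exactly 2 distinct arms are required")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        self.arms: tuple = tuple(arms)
        self.specs: list = list(specs)
        self.config = config
        self.units: list = []
        self._by_id: dict = {}
        self._alloc_order: list = []  # unit_ids in enrollment order
        self._arm_n = [0, 0]
        self._agg: dict = {s.name: _ArmAggregate(s) for s in self.specs}
        for u in units:
            self.add_unit(u)

    # -- unit management -------------------------------------------------

    def add_unit(self, unit: UnitRecord) -> None:
        if unit.unit_id in self._by_id:
            raise StateError(f"duplicate unit_id {unit.unit_id!r}")
        if unit.arm is not None and unit.arm not in self.arms:
            raise ConfigError(f"unit {unit.unit_id!r}: unknown arm {unit.arm!r}")
        if unit.is_randomized:
            # randomized units must arrive in enrollment order so the
            # gapless 0..k-1 invariant can be enforced incrementally
            if unit.enrollment_index is None:
                raise ConfigError(
                    f"unit {unit.unit_id!r}: randomized units need an enrollment_index"
                )
            if unit.enrollment_index != self.n_randomized:
                raise ConfigError(
                    f"unit {unit.unit_id!r}: enrollment_index {unit.enrollment_index} "
                    f"breaks the gapless 0..k-1 sequence (expected {self.n_randomized})"
                )
        self.units.append(unit)
        self._by_id[unit.unit_id] = unit
        if unit.is_randomized:
            self._alloc_order.append(unit.unit_id)
            self._ingest_allocation(unit)

    def unit(self, unit_id: str) -> UnitRecord:
        try:
            return self._by_id[unit_id]
        except KeyError:
            raise StateError(f"unknown unit {unit_id!r}") from None

    def get_unit(self, unit_id: str) -> Optional[UnitRecord]:
        return self._by_id.get(unit_id)

    def spec(self, name: str) -> CovariateSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise ConfigError(f"unknown covariate {name!r}")

    @property
    def n_randomized(self) -> int:
        return len(self._alloc_order)

    def arm_index(self, arm: str) -> int:
        try:
            return self.arms.index(arm)
        except ValueError:
            raise ConfigError(f"unknown arm {arm!r}") from None

    def arm_sizes(self) -> tuple:
        return tuple(self._arm_n)

    def randomized_units(self) -> list:
        """Randomized units in enrollment order."""
        return [self._by_id[uid] for uid in self._alloc_order]

    def aggregate(self, name: str) -> _ArmAggregate:
        return self._agg[name]

    # -- allocation recording --------------------------------------------

    def record_allocation(
        self,
        unit_id: str,
        arm: str,
        allocation_probability: float,
        criteria: Sequence[str],
        source: AllocationSource,
    ) -> UnitRecord:
        """Commit an allocation: the single funnel for both the algorithm
        and the backup list, so balance aggregates always stay in sync."""
        unit = self.unit(unit_id)
        if unit.is_randomized:
            raise StateError(f"unit {unit_id!r} is already randomized")
        if arm not in self.arms:
            raise ConfigError(f"unknown arm {arm!r}")
        unit.arm = arm
        unit.allocation_probability = float(allocation_probability)
        unit.criteria = list(criteria)
        unit.source = AllocationSource(source)
        unit.enrollment_index = self.n_randomized
        self._alloc_order.append(unit_id)
        self._ingest_allocation(unit)
        return unit

    def _ingest_allocation(self, unit: UnitRecord) -> None:
        ai = self.arm_index(unit.arm)
        self._arm_n[ai] += 1
        for spec in self.specs:
            v = unit.value(spec.name)
            if v is not None:
                self._agg[spec.name].add(ai, v)

    # -- (de)serialization -----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "arms": list(self.arms),
            "covariates": [
                {
                    "name": s.name,
                    "kind": s.kind.value,
                    "levels": list(s.levels),
                    "active_from": s.active_from,
                    "required": s.required,
                }
                for s in self.specs
            ],
            "msb": {
                "p_threshold": self.config.p_threshold,
                "biased_probability": self.config.biased_probability,
                "burn_in": self.config.burn_in,
                "size_balance": self.config.size_balance,
                "seed": self.config.seed,
            },
            "units": [unit_to_dict(u) for u in self.units],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialState":
        specs = [_spec_from_dict(c) for c in d.get("covariates", [])]
        config = _msb_from_dict(d.get("msb", {}))
        units = [unit_from_dict(u) for u in d.get("units", [])]
        units.sort(
            key=lambda u: (u.enrollment_index is None, u.enrollment_index or 0)
        )
        # randomized units must be ingested in enrollment order
        randomized = [u for u in units if u.is_randomized]
        pending = [u for u in units if not u.is_randomized]
        return cls(d["arms"], specs, config, randomized + pending)


def unit_to_dict(u: UnitRecord) -> dict:
    return {
        "unit_id": u.unit_id,
        "member_record_ids": list(u.member_record_ids),
        "covariates": dict(u.covariates),
        "ready": u.ready,
        "arm": u.arm,
        "allocation_probability": u.allocation_probability,
        "criteria": list(u.criteria) if u.criteria is not None else None,
        "source": u.source.value,
        "enrollment_index": u.enrollment_index,
    }


def unit_from_dict(d: Mapping) -> UnitRecord:
    return UnitRecord(
        unit_id=str(d["unit_id"]),
        member_record_ids=[str(r) for r in d.get("member_record_ids", [])],
        covariates=dict(d.get("covariates", {})),
        ready=bool(d.get("ready", False)),
        arm=d.get("arm"),
        allocation_probability=d.get("allocation_probability"),
        criteria=list(d["criteria"]) if d.get("criteria") is not None else None,
        source=AllocationSource(d.get("source", "unset")),
        enrollment_index=d.get("enrollment_index"),
    )


def _spec_from_dict(d: Mapping) -> CovariateSpec:
    try:
        kind = CovariateKind(d["kind"])
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"covariate {d.get('name', '?')!r}: bad kind: {exc}") from exc
    return CovariateSpec(
        name=str(d["name"]),
        kind=kind,
        levels=tuple(d.get("levels", ())),
        active_from=int(d.get("active_from", 0)),
        required=bool(d.get("required", True)),
    )


def _msb_from_dict(d: Mapping) -> MSBConfig:
    known = {"p_threshold", "biased_probability", "burn_in", "size_balance", "seed"}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown msb config keys: {sorted(unknown)}")
    return MSBConfig(**{k: d[k] for k in known if k in d})


def load_config(path) -> TrialState:
    """Load and validate a run configuration (JSON).

    Schema: ``{"arms": [str, str], "covariates": [spec...], "msb": {...}}``.
    Returns a TrialState with an empty unit list; omitted ``msb`` fields
    take the documented defaults (eta=0.3, p_b=0.7, burn_in=20,
    size_balance=true).
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
    for key in ("arms", "covariates"):
        if key not in raw:
            raise ConfigError(f"config missing required key {key!r}")
    if "units" in raw:
        raise ConfigError("run configurations carry no units; use the record store")
    return TrialState.from_dict(raw)


def validate_unit(state: TrialState, unit: UnitRecord) -> list:
    """Check a unit's covariates against the trial's specs.

    Returns a list of human-readable issues; an empty list means every
    required covariate is present and all supplied values conform
    (numeric for continuous, a declared level otherwise). Issues are
    returned, never raised: the caller decides whether they block
    randomization.
    """
    issues = []
    for spec in state.specs:
        v = unit.value(spec.name)
        if v is None:
            if spec.required:
                issues.append(f"missing required covariate {spec.name!r}")
            continue
        if spec.kind is CovariateKind.CONTINUOUS:
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                try:
                    float(v)
                except (TypeError, ValueError):
                    issues.append(
                        f"covariate {spec.name!r}: non-numeric value {v!r}"
                    )
        else:
            if str(v) not in spec.levels:
                issues.append(
                    f"covariate {spec.name!r}: value {v!r} not in levels {list(spec.levels)}"
                )
    return issues
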