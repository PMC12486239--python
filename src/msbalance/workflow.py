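"""Trigger-driven randomization workflow.

Emulates the automation loop of an EDC data-entry-trigger pipeline: a
saved "Randomization" form fires a URL-encoded notification carrying
the project id, record id and instrument name; the handler checks that
a randomization is actually required (right project, right form, unit
exists, randomization indicator set, not yet allocated), runs the MSB
engine, writes the allocation back to the record store, and appends an
audit-log entry. Every trigger produces exactly one log entry, and
re-delivery after a successful allocation is idempotent.

A pre-generated static backup list covers outages: an allocation taken
from the list is recorded with ``source = backup_list`` and thereafter
counts in every balance computation exactly as an algorithmic one
would (reconciliation).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union
from urllib.parse import parse_qsl

import numpy as np

from .engine import (
    AllocationRejected,
    AllocationResult,
    commit_allocation,
    propose_allocation,
)
from .model import (
    AllocationSource,
    MSBConfig,
    StateError,
    TrialState,
    UnitRecord,
    validate_unit,
)
from .store import StoreSnapshot, read_store, write_allocation

__all__ = [
    "TriggerPayload",
    "TriggerParseError",
    "Outcome",
    "AuditLogEntry",
    "AuditLog",
    "BackupList",
    "parse_trigger",
    "should_randomize",
    "handle_trigger",
    "generate_backup_list",
    "apply_backup_allocation",
    "consistency_check",
]

DEFAULT_FORM_NAME = "randomization"


class TriggerParseError(ValueError):
    pass


@dataclass(frozen=True)
class TriggerPayload:
    """Parsed data-entry-trigger notification."""

    project_id: str
    record_id: str
    instrument: str
    raw: str
    extras: Dict[str, str] = field(default_factory=dict)


def parse_trigger(raw: str) -> TriggerPayload:
    """Decode a URL-encoded trigger body.

    Required keys are ``project_id``, ``record`` and ``instrument``
    (percent-encoding is decoded); any other keys are preserved in
    ``extras`` and the original string in ``raw``.
    """
    pairs = dict(parse_qsl(raw, keep_blank_values=True))
    for key in ("project_id", "record", "instrument"):
        if not pairs.get(key):
            raise TriggerParseError(f"trigger payload missing required key {key!r}")
    extras = {
        k: v for k, v in pairs.items() if k not in {"project_id", "record", "instrument"}
    }
    return TriggerPayload(
        project_id=pairs["project_id"],
        record_id=pairs["record"],
        instrument=pairs["instrument"],
        raw=raw,
        extras=extras,
    )


class Outcome(str, Enum):
    RANDOMIZED = "randomized"
    IGNORED_WRONG_PROJECT = "ignored_wrong_project"
    IGNORED_WRONG_INSTRUMENT = "ignored_wrong_instrument"
    IGNORED_NOT_READY = "ignored_not_ready"
    IGNORED_ALREADY_RANDOMIZED = "ignored_already_randomized"
    REJECTED_VALIDATION = "rejected_validation"
    FAILED_ERROR = "failed_error"
    BACKUP_USED = "backup_used"


@dataclass
class AuditLogEntry:
    timestamp: str
    record_id: str
    outcome: Outcome
    detail: str = ""
    allocation: Optional[AllocationResult] = None

    def __post_init__(self) -> None:
        has_alloc = self.allocation is not None
        should = self.outcome in (Outcome.RANDOMIZED, Outcome.BACKUP_USED)
        if has_alloc != should:
            raise ValueError("allocation present iff outcome is randomized/backup_used")

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "record_id": self.record_id,
            "outcome": self.outcome.value,
            "detail": self.detail,
            "allocation": self.allocation.to_dict() if self.allocation else None,
        }


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


class AuditLog:
    """Append-only JSON-lines audit log."""

    def __init__(self, path: Union[str, Path]) -> None:
        self.path = Path(path)

    def append(self, entry: AuditLogEntry) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry.to_dict()) + "\n")

    def entries(self) -> List[dict]:
        if not self.path.exists():
            return []
        with open(self.path, "r", encoding="utf-8") as fh:
            return [json.loads(line) for line in fh if line.strip()]


def should_randomize(
    store: Union[str, Path, StoreSnapshot],
    payload: TriggerPayload,
    expected_project: str,
    form_name: str = DEFAULT_FORM_NAME,
) -> Tuple[bool, Optional[Outcome], str]:
    """Decide whether a trigger requires a randomization.

    True only when the project id matches, the instrument is the
    configured randomization form (case-insensitive), the record maps
    to a known unit whose randomization indicator is set, and no arm
    has been assigned yet. Otherwise false with the specific ignore
    outcome and a human-readable detail.
    """
    if str(payload.project_id) != str(expected_project):
        return False, Outcome.IGNORED_WRONG_PROJECT, (
            f"project {payload.project_id!r} != expected {expected_project!r}"
        )
    if payload.instrument.strip().lower() != form_name.strip().lower():
        return False, Outcome.IGNORED_WRONG_INSTRUMENT, (
            f"instrument {payload.instrument!r} is not the randomization form"
        )
    snapshot = store if isinstance(store, StoreSnapshot) else read_store(store)
    unit = snapshot.find_by_record(payload.record_id)
    if unit is None:
        return False, Outcome.IGNORED_NOT_READY, (
            f"record {payload.record_id!r} does not map to any unit"
        )
    if unit.arm is not None:
        return False, Outcome.IGNORED_ALREADY_RANDOMIZED, (
            f"unit {unit.unit_id!r} already allocated to {unit.arm!r}"
        )
    if not unit.ready:
        return False, Outcome.IGNORED_NOT_READY, (
            f"unit {unit.unit_id!r} randomization indicator not set"
        )
    return True, None, f"unit {unit.unit_id!r} ready for randomization"


def handle_trigger(
    store: Union[str, Path],
    payload: TriggerPayload,
    state: TrialState,
    config: MSBConfig,
    rng: np.random.Generator,
    log: AuditLog,
    expected_project: str,
    form_name: str = DEFAULT_FORM_NAME,
) -> AuditLogEntry:
    """Process one trigger end to end.

    Composes should_randomize -> validate_unit -> the MSB engine ->
    store write-back -> audit append. The store write happens before
    the in-memory state commit, so a write failure leaves the unit
    unrandomized everywhere and is logged as ``failed_error``. Exactly
    one log entry is appended per call; replaying a trigger after a
    successful allocation yields ``ignored_already_randomized`` with no
    state change.
    """
    record_id = payload.record_id
    try:
        snapshot = read_store(store)
        ok, outcome, detail = should_randomize(
            snapshot, payload, expected_project, form_name
        )
        if not ok:
            entry = AuditLogEntry(_now(), record_id, outcome, detail)
            log.append(entry)
            return entry
        store_unit = snapshot.find_by_record(record_id)
        unit = state.unit(store_unit.unit_id)
        issues = validate_unit(state, unit)
        if issues:
            entry = AuditLogEntry(
                _now(), record_id, Outcome.REJECTED_VALIDATION, "; ".join(issues)
            )
            log.append(entry)
            return entry
        result = propose_allocation(state, unit, rng)
        write_allocation(store, unit.unit_id, result, snapshot=snapshot)
        commit_allocation(state, result)
        entry = AuditLogEntry(
            _now(),
            record_id,
            Outcome.RANDOMIZED,
            f"unit {unit.unit_id!r} -> {result.arm!r}",
            allocation=result,
        )
        log.append(entry)
        return entry
    except AllocationRejected as exc:
        entry = AuditLogEntry(
            _now(), record_id, Outcome.REJECTED_VALIDATION, "; ".join(exc.issues)
        )
        log.append(entry)
        return entry
    except Exception as exc:  # noqa: BLE001 - every failure must be logged
        entry = AuditLogEntry(
            _now(), record_id, Outcome.FAILED_ERROR, f"{type(exc).__name__}: {exc}"
        )
        log.append(entry)
        return entry


@dataclass
class BackupList:
    """Pre-generated static 1:1 allocation list for outages."""

    entries: List[str]
    next_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.next_index <= len(self.entries):
            raise ValueError("next_index out of range")

    @property
    def exhausted(self) -> bool:
        return self.next_index >= len(self.entries)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "arm"])
            for i, arm in enumerate(self.entries):
                writer.writerow([i, arm])

    @classmethod
    def from_csv(
        cls, path: Union[str, Path], next_index: int = 0, seed: int = 0
    ) -> "BackupList":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            rows = sorted(reader, key=lambda r: int(r["index"]))
        return cls([r["arm"] for r in rows], next_index=next_index, seed=seed)


def generate_backup_list(
    n: int, seed: int, arms: Sequence[str] = ("intervention", "control")
) -> BackupList:
    """Draw ``n`` independent fair-coin allocations, deterministic under
    the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    entries = [arms[0] if u < 0.5 else arms[1] for u in rng.random(n)]
    return BackupList(entries=entries, seed=seed)


def apply_backup_allocation(
    state: TrialState, unit: UnitRecord, backup: BackupList
) -> AllocationResult:
    """Allocate a unit from the backup list during an outage.

    The unit takes the next unconsumed list entry at probability 0.5
    with no balance criteria; the list pointer advances. Once recorded,
    the unit counts among the randomized units in every subsequent
    balance computation, so the adaptive algorithm reconciles with the
    outage allocations when it resumes.
    """
    if backup.exhausted:
        raise StateError("backup list exhausted")
    if not unit.ready:
        raise StateError(f"unit {unit.unit_id!r} is not ready to be randomized")
    if unit.is_randomized:
        raise StateError(f"unit {unit.unit_id!r} is already randomized")
    arm = backup.entries[backup.next_index]
    result = AllocationResult(
        unit_id=unit.unit_id,
        arm=arm,
        probability_used=0.5,
        favored_arm=None,
        votes_arm0=0,
        votes_arm1=0,
        criteria=[],
        rng_draw=0.0,
        source=AllocationSource.BACKUP_LIST,
    )
    commit_allocation(state, result)
    backup.next_index += 1
    return result


def consistency_check(
    store: Union[str, Path], log: AuditLog
) -> List[str]:
    """Startup scan for store/log divergence.

    Flags units that carry an allocation in the store without a
    corresponding successful (randomized/backup_used) audit entry —
    the signature of a crash between the store write and the log
    append."""
    snapshot = read_store(store)
    logged = set()
    for e in log.entries():
        if e["outcome"] in (Outcome.RANDOMIZED.value, Outcome.BACKUP_USED.value):
            alloc = e.get("allocation") or {}
            logged.add(alloc.get("unit_id") or e["record_id"])
    warnings = []
    for u in snapshot.units:
        if u.arm is not None and u.unit_id not in logged and not (
            logged & set(u.member_record_ids)
        ):
            warnings.append(
                f"unit {u.unit_id!r} has arm {u.arm!r} but no successful audit entry"
            )
    return warnings
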