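"""Record-store readers/writers: the stand-in for the trial database.

The store holds one row per unit of randomization, in either CSV
(UTF-8, comma-separated, header row, RFC-4180 quoting; covariates in
``covariate.<name>`` columns, empty cells meaning missing) or an
equivalent JSON form. The two forms are losslessly interconvertible.

Writes use optimistic concurrency: a snapshot taken at read time
carries a content hash and a version counter (persisted in a sidecar
``<store>.meta.json``); an allocation write-back fails with
ConflictError — leaving the file byte-identical — if the store changed
underneath it. Successful writes are atomic (temp file + rename) and
bump the version by exactly 1.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

from .engine import AllocationResult
from .model import AllocationSource, UnitRecord, unit_from_dict, unit_to_dict

__all__ = [
    "StoreSnapshot",
    "StoreError",
    "ConflictError",
    "read_store",
    "write_store",
    "write_allocation",
]

_FIXED_COLUMNS = [
    "unit_id",
    "member_record_ids",
    "ready",
    "arm",
    "allocation_probability",
    "criteria",
    "source",
    "enrollment_index",
]
_COV_PREFIX = "covariate."


class StoreError(RuntimeError):
    pass


class ConflictError(StoreError):
    """The store changed between read and write; nothing was written."""


@dataclass
class StoreSnapshot:
    units: List[UnitRecord]
    version: int
    path: str
    content_hash: str = ""

    def unit(self, unit_id: str) -> Optional[UnitRecord]:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        return None

    def find_by_record(self, record_id: str) -> Optional[UnitRecord]:
        """Look a unit up by its own id or either member record id."""
        for u in self.units:
            if u.unit_id == record_id or record_id in u.member_record_ids:
                return u
        return None


def _meta_path(path: Union[str, Path]) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".meta.json")


def _read_version(path) -> int:
    mp = _meta_path(path)
    if not mp.exists():
        return 0
    with open(mp, "r", encoding="utf-8") as fh:
        return int(json.load(fh).get("version", 0))


def _write_version(path, version: int) -> None:
    tmp = _meta_path(path).with_suffix(".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump({"version": version}, fh)
    os.replace(tmp, _meta_path(path))


def _hash_file(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def _is_json(path) -> bool:
    return str(path).lower().endswith(".json")


def _parse_cell(cell: str):
    """Covariate cell -> float when numeric, else the raw string."""
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        return cell


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in {"1", "true", "yes"}


def read_store(path: Union[str, Path]) -> StoreSnapshot:
    """Parse a CSV or JSON record store into a snapshot.

    Raises StoreError on duplicate unit ids or a header that lacks the
    documented columns.
    """
    path = Path(path)
    if not path.exists():
        raise StoreError(f"store file {path} does not exist")
    if _is_json(path):
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        units = [unit_from_dict(d) for d in raw["units"]]
    else:
        units = []
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in _FIXED_COLUMNS if c not in header]
            if missing:
                raise StoreError(f"store {path} missing columns: {missing}")
            cov_cols = [c for c in header if c.startswith(_COV_PREFIX)]
            for row in reader:
                arm = row["arm"] or None
                crit_cell = row["criteria"]
                units.append(
                    UnitRecord(
                        unit_id=row["unit_id"],
                        member_record_ids=[
                            r for r in row["member_record_ids"].split(";") if r
                        ],
                        covariates={
                            c[len(_COV_PREFIX):]: _parse_cell(row[c])
                            for c in cov_cols
                            if row[c] != ""
                        },
                        ready=_parse_bool(row["ready"]),
                        arm=arm,
                        allocation_probability=(
                            float(row["allocation_probability"])
                            if row["allocation_probability"]
                            else None
                        ),
                        criteria=(
                            [c for c in crit_cell.split(";") if c]
                            if arm is not None
                            else None
                        ),
                        source=AllocationSource(row["source"] or "unset"),
                        enrollment_index=(
                            int(row["enrollment_index"])
                            if row["enrollment_index"]
                            else None
                        ),
                    )
                )
    ids = [u.unit_id for u in units]
    dups = {i for i in ids if ids.count(i) > 1}
    if dups:
        raise StoreError(f"duplicate unit_id(s) in {path}: {sorted(dups)}")
    return StoreSnapshot(
        units=units,
        version=_read_version(path),
        path=str(path),
        content_hash=_hash_file(path),
    )


def _covariate_columns(units: Sequence[UnitRecord]) -> List[str]:
    names: List[str] = []
    for u in units:
        for n in u.covariates:
            if n not in names:
                names.append(n)
    return names


def _write_file(path: Path, units: Sequence[UnitRecord]) -> None:
    tmp = path.with_name(path.name + ".tmp")
    if _is_json(path):
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump({"units": [unit_to_dict(u) for u in units]}, fh, indent=1)
            fh.write("\n")
    else:
        cov_names = _covariate_columns(units)
        with open(tmp, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_FIXED_COLUMNS + [_COV_PREFIX + n for n in cov_names])
            for u in units:
                writer.writerow(
                    [
                        u.unit_id,
                        ";".join(u.member_record_ids),
                        "true" if u.ready else "false",
                        u.arm or "",
                        "" if u.allocation_probability is None else repr(u.allocation_probability),
                        ";".join(u.criteria) if u.criteria else "",
                        "" if u.source is AllocationSource.UNSET else u.source.value,
                        "" if u.enrollment_index is None else u.enrollment_index,
                    ]
                    + [
                        "" if u.value(n) is None else u.value(n)
                        for n in cov_names
                    ]
                )
    os.replace(tmp, path)


def write_store(path: Union[str, Path], units: Sequence[UnitRecord]) -> int:
    """Write (or overwrite) the whole store atomically; returns the new
    version."""
    path = Path(path)
    version = (_read_version(path) + 1) if path.exists() else 1
    _write_file(path, units)
    _write_version(path, version)
    return version


def write_allocation(
    path: Union[str, Path],
    unit_id: str,
    result: AllocationResult,
    snapshot: Optional[StoreSnapshot] = None,
) -> int:
    """Persist one allocation write-back; returns the new store version.

    Re-reads the file, verifies the unit exists and is unallocated,
    and — when ``snapshot`` is supplied — that the file is unchanged
    since that snapshot was taken (otherwise ConflictError and no
    write). Only the unit's allocation fields change; all other rows
    are rewritten byte-identically.
    """
    path = Path(path)
    if snapshot is not None and _hash_file(path) != snapshot.content_hash:
        raise ConflictError(f"store {path} changed since snapshot; not writing")
    current = read_store(path)
    unit = current.unit(unit_id)
    if unit is None:
        raise StoreError(f"unit {unit_id!r} not found in {path}")
    if unit.arm is not None:
        raise StoreError(f"unit {unit_id!r} already has an allocation")
    unit.arm = result.arm
    unit.allocation_probability = result.arm_probability
    unit.criteria = list(result.criteria)
    unit.source = result.source
    unit.enrollment_index = _next_enrollment_index(current.units)
    _write_file(path, current.units)
    new_version = current.version + 1
    _write_version(path, new_version)
    return new_version


def _next_enrollment_index(units: Sequence[UnitRecord]) -> int:
    taken = [u.enrollment_index for u in units if u.enrollment_index is not None]
    return (max(taken) + 1) if taken else 0
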