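"""Shared fixtures: engineered trial states and a run configuration."""

from __future__ import annotations

import json

import pytest

from msbalance import (
    AllocationSource,
    CovariateKind,
    CovariateSpec,
    MSBConfig,
    TrialState,
    UnitRecord,
)


def make_binary_state(
    k0: int,
    n0: int,
    k1: int,
    n1: int,
    config: MSBConfig | None = None,
    arms=("A", "B"),
    name: str = "trait",
) -> TrialState:
    """A trial with one binary covariate and a fixed per-arm split:
    k0/n0 trait-positive units in arm 0, k1/n1 in arm 1."""
    spec = CovariateSpec(name, CovariateKind.BINARY, ("no", "yes"))
    state = TrialState(arms, [spec], config or MSBConfig(size_balance=False))
    uid = 0
    for arm, (k, n) in zip(arms, [(k0, n0), (k1, n1)]):
        for j in range(n):
            u = UnitRecord(
                f"u{uid}", ready=True, covariates={name: "yes" if j < k else "no"}
            )
            state.add_unit(u)
            state.record_allocation(u.unit_id, arm, 0.5, [], AllocationSource.ALGORITHM)
            uid += 1
    return state


def make_continuous_state(
    values0,
    values1,
    config: MSBConfig | None = None,
    arms=("A", "B"),
    name: str = "age",
) -> TrialState:
    """A trial with one continuous covariate and fixed per-arm values."""
    spec = CovariateSpec(name, CovariateKind.CONTINUOUS)
    state = TrialState(arms, [spec], config or MSBConfig(size_balance=False))
    uid = 0
    for arm, values in zip(arms, [values0, values1]):
        for v in values:
            u = UnitRecord(f"u{uid}", ready=True, covariates={name: float(v)})
            state.add_unit(u)
            state.record_allocation(u.unit_id, arm, 0.5, [], AllocationSource.ALGORITHM)
            uid += 1
    return state


def new_unit(unit_id: str, **covariates) -> UnitRecord:
    return UnitRecord(unit_id, ready=True, covariates=covariates)


@pytest.fixture
def config_file(tmp_path):
    """A minimal valid run configuration on disk."""
    cfg = {
        "arms": ["intervention", "control"],
        "covariates": [
            {"name": "age", "kind": "continuous"},
            {"name": "prep_use", "kind": "binary", "levels": ["no", "yes"]},
            {
                "name": "status",
                "kind": "categorical",
                "levels": ["single", "partnered_alone", "dyad"],
            },
        ],
        "msb": {"p_threshold": 0.3, "burn_in": 2, "seed": 7},
    }
    path = tmp_path / "config.json"
    path.write_text(json.dumps(cfg))
    return path
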