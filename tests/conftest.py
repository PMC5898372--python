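"""Shared fixtures and cohort-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dicohort import DiscreteCohort, VariableSchema


def build_cohort(columns: dict[str, tuple], kinds: dict[str, str] | None = None,
                 raw: pd.DataFrame | None = None) -> DiscreteCohort:
    """Assemble a cohort from ``name -> (states, values)`` mappings."""
    kinds = kinds or {}
    schema = []
    data = {}
    n = None
    for name, (states, values) in columns.items():
        kind = kinds.get(name, "categorical")
        if kind == "response":
            schema.append(VariableSchema(name, "response", ("Res", "NonRes")))
        else:
            schema.append(VariableSchema(name, kind, tuple(states)))
        data[name] = list(values)
        n = len(values)
    index = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    if raw is not None:
        raw = raw.set_index(index)
    return DiscreteCohort(schema, pd.DataFrame(data, index=index), raw=raw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-like synthetic cohort, shared across read-only tests."""
    from dicohort import assemble_cohort

    cohort, truth = assemble_cohort(seed=11)
    return cohort, truth
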