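"""Shared fixtures: modulation curves, small grids, and cached scenario runs.

The full-scenario fixtures run the coupled simulator once per session at
the coarse desk-scale mesh and are shared by the outcome and invariant
tests, which keeps the suite inside a few minutes.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import osteosim as o

logging.getLogger("osteosim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def modulation() -> o.ModulationSet:
    return o.ModulationSet()


@pytest.fixture()
def small_grid() -> o.Grid:
    return o.Grid(np.linspace(0.0, 2.0, 6), np.linspace(0.0, 1.2, 4))


@pytest.fixture(scope="session")
def scenario_runs():
    """Lazily computed, cached scenario outcomes keyed by label."""
    cache: dict[str, o.RunSummary] = {}

    def get(label: str) -> o.RunSummary:
        if label not in cache:
            if label == "small_gap":
                sc = o.small_gap_scenario()
            elif label == "empty":
                sc = o.critical_defect_scenario(dose_ug=0.0, gel=False)
            elif label.startswith("gel_"):
                dose = float(label.split("_", 1)[1])
                sc = o.critical_defect_scenario(dose_ug=dose, gel=True)
            else:  # pragma: no cover - guard against typos in tests
                raise KeyError(label)
            cache[label] = o.run(sc)
        return cache[label]

    return get
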