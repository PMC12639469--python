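"""Shared fixtures: small analytic grids and cached end-to-end cases.

The two end-to-end fixtures run the full compare pipeline (plan both
modalities, sweep the VHEE pulse repetition frequency) once per session;
several acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from flashpbs.grids import StructureSet, VoxelGrid
from flashpbs.pipeline import compare_modalities


@pytest.fixture
def water_box():
    """40^3 uniform water grid at 2 mm with a central cubic PTV."""
    vals = np.ones((40, 40, 40))
    grid = VoxelGrid(vals, (2.0, 2.0, 2.0), (-39.0, -39.0, -39.0))
    body = np.ones(grid.dims, dtype=bool)
    ptv = np.zeros(grid.dims, dtype=bool)
    ptv[15:25, 15:25, 15:25] = True
    return grid, StructureSet(grid, {"BODY": body, "PTV": ptv})


@pytest.fixture(scope="session")
def brain_case():
    """Brain-like preset: proton plan + VHEE 200 MeV at PRF 100 Hz."""
    fi_table, metric_table, deliveries = compare_modalities(
        "brain_like", prf_values_Hz=(100,), seed=1
    )
    return fi_table, metric_table, deliveries


@pytest.fixture(scope="session")
def prostate_case():
    """Prostate-like preset: proton plan + VHEE PRF sweep 100/500/1000 Hz."""
    fi_table, metric_table, deliveries = compare_modalities(
        "prostate_like", prf_values_Hz=(100, 500, 1000), seed=1
    )
    return fi_table, metric_table, deliveries
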