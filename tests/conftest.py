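"""Shared fixtures: probe geometry and session-scoped synthetic populations.

The expensive class-contrast population (50 PYR + 50 PV, 400 s) is generated
once per session and shared by the recovery, ordering, and classification
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from deltaspike import (
    PopulationSpec,
    chunk_feature_table,
    default_probe,
    generate_population,
    null_params,
    unit_feature_table,
)


@pytest.fixture(scope="session")
def geometry():
    return default_probe()


@pytest.fixture(scope="session")
def population(geometry):
    """Class-contrast labeled population: 50 PYR + 50 PV units."""
    spec = PopulationSpec(n_pyr=50, n_pv=50, duration_s=400.0, seed=0, geometry=geometry)
    return generate_population(spec)


@pytest.fixture(scope="session")
def nochunk_table(population, geometry):
    return unit_feature_table(population, geometry)


@pytest.fixture(scope="session")
def chunk25_table(population, geometry):
    return chunk_feature_table(population, 25, geometry, seed=1)


@pytest.fixture(scope="session")
def null_population(geometry):
    """Both classes drawn from one generative model: no label information."""
    spec = PopulationSpec(n_pyr=40, n_pv=40, duration_s=300.0, seed=2, geometry=geometry)
    return generate_population(spec, null_params("PYR"), null_params("PV"))


@pytest.fixture(scope="session")
def small_population(geometry):
    """A cheap population for plumbing tests (10 units, short trains)."""
    spec = PopulationSpec(n_pyr=6, n_pv=4, duration_s=120.0, seed=5, geometry=geometry)
    return generate_population(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
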