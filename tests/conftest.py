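"""Shared fixtures: small planted references and simulation conditions."""

import pytest

from msikit.catalog import catalog_by_id
from msikit.simulate import (
    MMR_DEFICIENT_MODEL,
    STABLE_MODEL,
    SYNTHETIC_REPORTER,
    random_plants,
    simulate_reference,
    synthetic_catalog,
)


@pytest.fixture(scope="session")
def planted_reference():
    """Two 8-kb chromosomes with 60 planted repeat tracts and their truth."""
    plants = random_plants(60, 2, 8000, seed=42)
    sequences, truth = simulate_reference(2, 8000, plants, seed=42)
    return sequences, truth


@pytest.fixture(scope="session")
def msi_catalog():
    """Virtual mono-A catalog: unit counts 5-15, 11 loci each (121 loci)."""
    return synthetic_catalog({"A": range(5, 16)}, loci_per_unit_count=11)


@pytest.fixture(scope="session")
def msi_catalog_by_id(msi_catalog):
    return catalog_by_id(msi_catalog)


@pytest.fixture(scope="session")
def reporter_reference():
    return SYNTHETIC_REPORTER


@pytest.fixture(scope="session")
def stable_model():
    return STABLE_MODEL


@pytest.fixture(scope="session")
def deficient_model():
    return MMR_DEFICIENT_MODEL
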