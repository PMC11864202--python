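"""Shared fixtures: dataset builders and deterministic hypothesis profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssdbench.ingest import ChemicalDataset, TaxonGroup

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_GROUP_CYCLE = (
    TaxonGroup.FISH,
    TaxonGroup.INVERTEBRATE,
    TaxonGroup.ALGAE,
    TaxonGroup.AMPHIBIAN,
)


def make_dataset(values, groups=None, chemical_id="chem") -> ChemicalDataset:
    """Build a ChemicalDataset from raw values; groups cycle over all four."""
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = [_GROUP_CYCLE[i % 4] for i in range(len(values))]
    return ChemicalDataset(
        chemical_id=chemical_id,
        species_values=tuple(
            (f"sp_{i:04d}", g, float(v)) for i, (g, v) in enumerate(zip(groups, values))
        ),
    )


@pytest.fixture
def lognormal_dataset():
    """60 species drawn from a log-normal sensitivity model, all 4 groups."""
    rng = np.random.default_rng(42)
    return make_dataset(np.exp(rng.normal(3.0, 1.5, size=60)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
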