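"""Shared fixtures: toy structures and a scaled-down seeded reference run."""

from __future__ import annotations

import numpy as np
import pytest

from shp2meta.synthetic import (
    ToyProteinSpec,
    make_metad_reference_run,
    make_toy_protein,
)


@pytest.fixture(scope="session")
def toy_spec() -> ToyProteinSpec:
    return ToyProteinSpec(seed=2024)


@pytest.fixture(scope="session")
def toy_closed(toy_spec):
    return make_toy_protein(toy_spec, "closed")


@pytest.fixture(scope="session")
def toy_open(toy_spec):
    return make_toy_protein(toy_spec, "open")


@pytest.fixture(scope="session")
def short_reference_run():
    """A shortened double-well reference run for unit-level engine checks
    (the full-length run is exercised by the acceptance suite)."""
    return make_metad_reference_run(seed=11, n_steps=200_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
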