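"""Shared fixtures: small lattices and helpers to build hand-laid states."""

from __future__ import annotations

import numpy as np
import pytest

from glioinvade.model_core import LatticeGeometry, TumourState


@pytest.fixture
def small_geometry() -> LatticeGeometry:
    """A 21 x 21 lattice (0.42 mm at 20 um resolution)."""
    return LatticeGeometry(side_mm=0.42, site_um=20.0)


@pytest.fixture
def small_state(small_geometry) -> TumourState:
    return TumourState(small_geometry)


def place(state: TumourState, sites, phenotype: int = 0, age_h: float = 0.0):
    """Place one cell per (i, j) site; returns the new cell ids."""
    return [state.add_cell(i, j, phenotype, age_h) for i, j in sites]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
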