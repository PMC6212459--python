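"""Synthetic phantom spheroids with known ground-truth morphometrics.

Phantoms are grid-native occupancy states built by construction —
a filled disc, a disc plus detached singleton cells (starburst-like),
or a disc with cohesive finger-like sprouts (primary-like) — each
shipped with the metric values implied by its construction, so the
morphometrics layer can be validated independently of the simulator.
"""

from __future__ import annotations

import numpy as np

from .model_core import EMPTY, LatticeGeometry, TumourState

__all__ = ["make_disc", "make_starburst", "make_sprouted"]


def _blank_state(h_um: float, side_mm: float) -> TumourState:
    return TumourState(LatticeGeometry(side_mm=side_mm, site_um=h_um))


def _fill_disc(state: TumourState, radius_um: float, phenotype: int) -> float:
    """Occupy all sites within ``radius_um`` of the centre; returns the
    construction ground-truth maximum site-centre distance (um)."""
    geom = state.geometry
    ci, cj = geom.centre_site
    h = geom.site_um
    r_sites = int(np.floor(radius_um / h)) + 1
    max_d = 0.0
    for di in range(-r_sites, r_sites + 1):
        for dj in range(-r_sites, r_sites + 1):
            d = float(np.hypot(di, dj)) * h
            if d <= radius_um + 1e-9:
                state.add_cell(ci + di, cj + dj, phenotype)
                max_d = max(max_d, d)
    return max_d


def make_disc(
    radius_um: float,
    h_um: float = 20.0,
    side_mm: float = 5.0,
    phenotype: int = 7,
) -> tuple[TumourState, dict]:
    """Fully packed disc; mirrors the simulator's initial condition.

    Returns ``(state, truth)`` where ``truth`` records the exact
    invasive/core radius (equal, by construction) and cell count.
    """
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    if radius_um >= side_mm * 1000.0 / 2.0:
        raise ValueError("disc does not fit inside the domain")
    state = _blank_state(h_um, side_mm)
    max_d = _fill_disc(state, radius_um, phenotype)
    truth = {
        "invasive_radius_um": max_d,
        "core_radius_um": max_d,
        "n_cells": state.n_live,
        "n_components": 1 if state.n_live else 0,
    }
    return state, truth


def make_starburst(
    core_radius_um: float,
    n_singletons: int,
    max_range_um: float,
    rng: np.random.Generator,
    h_um: float = 20.0,
    side_mm: float = 5.0,
    core_phenotype: int = 7,
    singleton_phenotype: int = 0,
) -> tuple[TumourState, dict]:
    """Disc plus detached single cells at known distances (starburst-like).

    Singletons are placed at uniformly random angles and radii in
    (core + 3h, max_range], rejected if they would touch the core or an
    earlier singleton, so each remains its own 8-connected component.
    """
    if max_range_um <= core_radius_um + 3 * h_um and n_singletons > 0:
        raise ValueError("max_range must exceed the core by at least 3 sites")
    state = _blank_state(h_um, side_mm)
    core_d = _fill_disc(state, core_radius_um, core_phenotype)
    geom = state.geometry
    ci, cj = geom.centre_site
    n = geom.n
    singleton_d = []
    attempts = 0
    while len(singleton_d) < n_singletons:
        attempts += 1
        if attempts > 10000 * max(1, n_singletons):
            raise RuntimeError("could not place isolated singletons; widen max_range")
        r_um = rng.uniform(core_radius_um + 3 * h_um, max_range_um)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        i = ci + int(round(r_um * np.cos(theta) / h_um))
        j = cj + int(round(r_um * np.sin(theta) / h_um))
        if not (1 <= i < n - 1 and 1 <= j < n - 1):
            continue
        neighbourhood = state.occ[i - 1 : i + 2, j - 1 : j + 2]
        if (neighbourhood != EMPTY).any():
            continue
        state.add_cell(i, j, singleton_phenotype)
        singleton_d.append(float(np.hypot(i - ci, j - cj)) * h_um)
    truth = {
        "invasive_radius_um": max([core_d, *singleton_d]),
        "core_radius_um": core_d,
        "n_cells": state.n_live,
        "n_components": 1 + len(singleton_d),
        "singleton_distances_um": sorted(singleton_d),
    }
    return state, truth


def make_sprouted(
    core_radius_um: float,
    n_sprouts: int,
    sprout_length_um: float,
    rng: np.random.Generator,
    h_um: float = 20.0,
    side_mm: float = 5.0,
    core_phenotype: int = 6,
    sprout_phenotype: int = 4,
) -> tuple[TumourState, dict]:
    """Connected disc with cohesive finger-like radial protrusions.

    Sprouts are single-cell-wide 8-connected chains marching outward
    from the disc rim at evenly spaced, randomly rotated angles; the
    whole phantom is one 8-connected component and its invasive radius
    equals core + sprout_length to within one site.
    """
    state = _blank_state(h_um, side_mm)
    core_d = _fill_disc(state, core_radius_um, core_phenotype)
    geom = state.geometry
    ci, cj = geom.centre_site
    n = geom.n
    max_d = core_d
    offset = rng.uniform(0.0, 2.0 * np.pi)
    for s in range(n_sprouts):
        theta = offset + 2.0 * np.pi * s / max(1, n_sprouts)
        ux, uy = np.cos(theta), np.sin(theta)
        # march in half-site increments so consecutive sites stay 8-adjacent
        r = core_radius_um
        tip = core_radius_um + sprout_length_um
        while r <= tip:
            i = ci + int(round(r * ux / h_um))
            j = cj + int(round(r * uy / h_um))
            if not (0 <= i < n and 0 <= j < n):
                break
            if state.occ[i, j] == EMPTY:
                state.add_cell(i, j, sprout_phenotype)
                max_d = max(max_d, float(np.hypot(i - ci, j - cj)) * h_um)
            r += h_um / 2.0
    truth = {
        "invasive_radius_um": max_d,
        "core_radius_um": max_d,  # one connected component
        "n_cells": state.n_live,
        "n_components": 1,
        "tip_radius_um": core_radius_um + sprout_length_um,
    }
    return state, truth
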