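"""Adhesion-gated random cell movement.

Unbiased cell motility is modelled as Fickian diffusion of the cell
density, dc/dt = D_c * laplacian(c).  The standard 5-point
discretisation turns D_c into a per-substep hop probability
``p_move = 4 * D_c * k / h^2`` for an individual cell, with the substep
length ``k`` chosen so that p_move <= 1.  Adhesion then gates the hop:
a cell may only relocate to an empty Moore-adjacent site whose number
of occupied neighbours (the mover itself excluded) equals the cell's
adhesion preference, and it picks uniformly among the admissible sites.
A cell whose admissible set is empty forfeits the attempt — it does not
fall back to a non-matching empty site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model_core import EMPTY, TumourState

__all__ = [
    "MoveKernel",
    "build_kernel",
    "occupied_neighbours",
    "admissible_destinations",
    "attempt_move",
]

MOORE_OFFSETS = tuple(
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
)


@dataclass(frozen=True)
class MoveKernel:
    """Discretised motility for one update interval.

    Attributes
    ----------
    d_c_cm2_s:
        Cell diffusion coefficient.
    k_s:
        Substep length in seconds.
    n_substeps:
        Substeps per update interval (n_substeps * k_s = t_r).
    p_move:
        Probability that a motile attempt occurs in one substep,
        4*D_c*k/h^2 <= 1.
    """

    d_c_cm2_s: float
    k_s: float
    n_substeps: int
    p_move: float


def build_kernel(d_c_cm2_s: float, h_um: float, t_r_h: float) -> MoveKernel:
    """Derive the per-substep hop probability from a diffusion coefficient.

    The substep is the largest k <= t_r with 4*D_c*k/h^2 <= 1, adjusted
    so an integer number of substeps tiles the update interval exactly.
    """
    if d_c_cm2_s < 0 or h_um <= 0 or t_r_h <= 0:
        raise ValueError("require D_c >= 0, h > 0 and t_r > 0")
    if d_c_cm2_s == 0.0:
        return MoveKernel(0.0, t_r_h * 3600.0, 1, 0.0)
    t_r_s = t_r_h * 3600.0
    h_cm = h_um * 1e-4
    k_bound = h_cm**2 / (4.0 * d_c_cm2_s)
    k = min(t_r_s, k_bound)
    n_substeps = int(np.ceil(t_r_s / k))
    k = t_r_s / n_substeps
    p_move = 4.0 * d_c_cm2_s * k / h_cm**2
    return MoveKernel(d_c_cm2_s, k, n_substeps, p_move)


def occupied_neighbours(state: TumourState, site: tuple[int, int], excluding: int | None = None) -> int:
    """Count live cells on Moore-adjacent sites of ``site``.

    ``excluding`` is a cell id ignored wherever it sits (the mover under
    study).  Off-lattice neighbours count as empty.
    """
    i, j = site
    n = state.geometry.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"site {site} outside the lattice")
    exclude = -2 if excluding is None else int(excluding)
    return int(_kernels.count_occupied_neighbours(state.occ, int(i), int(j), exclude))


def admissible_destinations(state: TumourState, cell_id: int) -> set[tuple[int, int]]:
    """Empty adjacent sites whose neighbour count matches the cell's preference."""
    if not state.alive[cell_id]:
        raise ValueError(f"cell {cell_id} is not alive")
    ci, cj = int(state.pos_i[cell_id]), int(state.pos_j[cell_id])
    pref = int(state.phenotype[cell_id])
    n = state.geometry.n
    out = set()
    for di, dj in MOORE_OFFSETS:
        ni, nj = ci + di, cj + dj
        if not (0 <= ni < n and 0 <= nj < n):
            continue
        if state.occ[ni, nj] != EMPTY:
            continue
        if occupied_neighbours(state, (ni, nj), excluding=cell_id) == pref:
            out.add((ni, nj))
    return out


def attempt_move(
    state: TumourState,
    cell_id: int,
    kernel: MoveKernel,
    rng: np.random.Generator,
    *,
    log: bool = False,
) -> TumourState:
    """Run one update interval's worth of movement substeps for one cell.

    The registry and occupancy grid are updated atomically per hop.
    With ``log=True`` the net displacement over the interval is appended
    to the event log (per-hop logging is deliberately not kept, to bound
    log size).
    """
    if not state.alive[cell_id]:
        raise ValueError(f"cell {cell_id} is not alive")
    before = (int(state.pos_i[cell_id]), int(state.pos_j[cell_id]))
    perm = np.asarray([cell_id], dtype=np.int64)
    _kernels.movement_pass(
        state.occ,
        state.pos_i,
        state.pos_j,
        state.alive,
        state.phenotype,
        perm,
        kernel.n_substeps,
        kernel.p_move,
        rng,
    )
    after = (int(state.pos_i[cell_id]), int(state.pos_j[cell_id]))
    if log and after != before:
        state.events.append((state.time_h, "move", int(cell_id), {"from": before, "to": after}))
    return state
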