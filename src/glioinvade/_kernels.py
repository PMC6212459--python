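"""Numba-compiled inner loops for cell movement and the life cycle.

These kernels operate directly on the structure-of-arrays registry held
by :class:`~glioinvade.model_core.TumourState` and consume randomness
from a ``numpy.random.Generator`` passed in from the caller, so a run is
fully reproducible from one seed regardless of which Python-level entry
point drives them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["movement_pass", "lifecycle_pass", "count_occupied_neighbours"]


@njit(cache=True)
def count_occupied_neighbours(occ, si, sj, exclude_id):
    """Occupied Moore neighbours of (si, sj), not counting ``exclude_id``.

    Sites beyond the lattice border count as empty (truncated
    neighbourhood).
    """
    n0 = occ.shape[0]
    n1 = occ.shape[1]
    count = 0
    for di in range(-1, 2):
        for dj in range(-1, 2):
            if di == 0 and dj == 0:
                continue
            ni = si + di
            nj = sj + dj
            if ni < 0 or nj < 0 or ni >= n0 or nj >= n1:
                continue
            v = occ[ni, nj]
            if v >= 0 and v != exclude_id:
                count += 1
    return count


@njit(cache=True)
def _move_cell(occ, pos_i, pos_j, idx, pref, n_substeps, p_move, rng):
    """Run all movement substeps for one cell; returns number of hops.

    Per substep: with probability ``p_move`` the cell attempts a hop to
    an empty Moore-adjacent site whose occupied-neighbour count (self
    excluded) equals its adhesion preference; among admissible sites one
    is chosen uniformly.  An empty admissible set forfeits the substep.
    """
    n0 = occ.shape[0]
    n1 = occ.shape[1]
    ci = pos_i[idx]
    cj = pos_j[idx]
    hops = 0
    cand_i = np.empty(8, dtype=np.int64)
    cand_j = np.empty(8, dtype=np.int64)
    for _ in range(n_substeps):
        if rng.random() >= p_move:
            continue
        n_cand = 0
        for di in range(-1, 2):
            for dj in range(-1, 2):
                if di == 0 and dj == 0:
                    continue
                ni = ci + di
                nj = cj + dj
                if ni < 0 or nj < 0 or ni >= n0 or nj >= n1:
                    continue
                if occ[ni, nj] != -1:
                    continue
                if count_occupied_neighbours(occ, ni, nj, idx) == pref:
                    cand_i[n_cand] = ni
                    cand_j[n_cand] = nj
                    n_cand += 1
        if n_cand == 0:
            continue
        pick = int(rng.random() * n_cand)
        occ[ci, cj] = -1
        ci = cand_i[pick]
        cj = cand_j[pick]
        occ[ci, cj] = idx
        hops += 1
    pos_i[idx] = ci
    pos_j[idx] = cj
    return hops


@njit(cache=True)
def movement_pass(occ, pos_i, pos_j, alive, phen, perm, n_substeps, p_move, rng):
    """Movement pass over cells in ``perm`` order; returns total hops."""
    total = 0
    if p_move <= 0.0:
        return 0
    for k in range(perm.shape[0]):
        idx = perm[k]
        if not alive[idx]:
            continue
        total += _move_cell(occ, pos_i, pos_j, idx, phen[idx], n_substeps, p_move, rng)
    return total


@njit(cache=True)
def lifecycle_pass(
    occ,
    pos_i,
    pos_j,
    alive,
    phen,
    age,
    quiescent,
    perm,
    n_cells,
    t_r,
    t_p_by_phen,
    radius,
    p_mut,
    switch_targets,
    rng,
    div_parent,
    div_child,
    div_phen,
    div_switched,
):
    """Proliferation pass over cells in ``perm`` order.

    A cell younger than its proliferation age simply ages by ``t_r``.
    A ready cell (age >= T_p, or already quiescent) searches the Moore
    neighbourhood of ``radius`` for an empty site: none found makes it
    quiescent (age frozen); otherwise a daughter is placed on a
    uniformly chosen empty site, both cells' ages reset to zero, and
    with probability ``p_mut`` a phenotype sampled uniformly from
    ``switch_targets`` is assigned to both daughters.

    Registry arrays must have capacity for ``n_cells + len(perm)`` rows.
    Returns ``(new_n_cells, n_divisions)``; division details are written
    into the ``div_*`` buffers.
    """
    n0 = occ.shape[0]
    n1 = occ.shape[1]
    side = 2 * radius + 1
    max_sites = side * side - 1
    cand_i = np.empty(max_sites, dtype=np.int64)
    cand_j = np.empty(max_sites, dtype=np.int64)
    n_div = 0
    n_targets = switch_targets.shape[0]
    for k in range(perm.shape[0]):
        idx = perm[k]
        if not alive[idx]:
            continue
        if not quiescent[idx] and age[idx] < t_p_by_phen[phen[idx]]:
            age[idx] += t_r
            continue
        ci = pos_i[idx]
        cj = pos_j[idx]
        n_cand = 0
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                if di == 0 and dj == 0:
                    continue
                ni = ci + di
                nj = cj + dj
                if ni < 0 or nj < 0 or ni >= n0 or nj >= n1:
                    continue
                if occ[ni, nj] == -1:
                    cand_i[n_cand] = ni
                    cand_j[n_cand] = nj
                    n_cand += 1
        if n_cand == 0:
            quiescent[idx] = True
            continue
        pick = int(rng.random() * n_cand)
        ni = cand_i[pick]
        nj = cand_j[pick]
        child = n_cells
        n_cells += 1
        if p_mut > 0.0 and rng.random() < p_mut:
            new_p = switch_targets[int(rng.random() * n_targets)]
            switched = True
        else:
            new_p = phen[idx]
            switched = False
        phen[idx] = new_p
        age[idx] = 0.0
        quiescent[idx] = False
        pos_i[child] = ni
        pos_j[child] = nj
        phen[child] = new_p
        age[child] = 0.0
        quiescent[child] = False
        alive[child] = True
        occ[ni, nj] = child
        div_parent[n_div] = idx
        div_child[n_div] = child
        div_phen[n_div] = new_p
        div_switched[n_div] = switched
        n_div += 1
    return n_cells, n_div
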