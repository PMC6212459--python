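"""Cell life cycle: age-based proliferation, quiescence, mitotic
phenotype switching and hypoxia-triggered death.

A cell divides once its age reaches the proliferation time T_p,
provided an empty site exists in its Moore neighbourhood of radius r
(r = 2, i.e. 24 surrounding sites, by default).  With no free site the
cell turns quiescent and keeps watching for space: the moment a site
frees up it divides.  At mitosis, with probability ``p_mut`` the
adhesion phenotype is redrawn uniformly from an allowed set and applied
to *both* daughters; otherwise both inherit the parent's phenotype.
Cells on sites whose oxygen has fallen below the lethal threshold die
and leave empty space behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import TumourState, validate_phenotype
from .oxygen import OxygenField, hypoxic_mask

__all__ = ["SwitchRule", "apply_phenotype_switch", "attempt_division", "apply_hypoxic_death"]


@dataclass(frozen=True)
class SwitchRule:
    """Stochastic phenotype reassignment at mitosis.

    With probability ``p_mut`` a phenotype is drawn uniformly from
    ``targets`` (self-transitions allowed) and given to both daughter
    cells.
    """

    p_mut: float = 0.0
    targets: tuple[int, ...] = (0, 1, 6, 7)

    def __post_init__(self):
        if not (0.0 <= self.p_mut <= 1.0):
            raise ValueError("p_mut must lie in [0, 1]")
        if not self.targets:
            raise ValueError("switch target set must be non-empty")
        for p in self.targets:
            validate_phenotype(p)

    def targets_array(self) -> np.ndarray:
        return np.asarray(self.targets, dtype=np.int8)


def apply_phenotype_switch(parent: int, switch: SwitchRule, rng: np.random.Generator) -> int:
    """Phenotype handed to both daughters at one mitosis event."""
    validate_phenotype(parent)
    if switch.p_mut > 0.0 and rng.random() < switch.p_mut:
        targets = switch.targets
        return int(targets[int(rng.random() * len(targets))])
    return int(parent)


def _t_p_array(t_p_h) -> np.ndarray:
    out = np.full(8, np.inf, dtype=np.float64)
    if np.isscalar(t_p_h):
        out[:] = float(t_p_h)
    else:
        for p, v in t_p_h.items():
            out[int(p)] = float(v)
    return out


def attempt_division(
    state: TumourState,
    cell_id: int,
    t_p_h,
    r: int,
    switch: SwitchRule,
    rng: np.random.Generator,
    *,
    t_r_h: float = 0.8,
) -> TumourState:
    """One life-cycle visit for one cell (ageing, quiescence or division).

    ``t_p_h`` is the proliferation age in hours — a scalar, or a mapping
    from phenotype to hours to express phenotype-dependent proliferation
    (e.g. selectively slowing the middle-adhesive classes).
    """
    if r < 1:
        raise ValueError("proliferation neighbourhood radius must be >= 1")
    if not state.alive[cell_id]:
        raise ValueError(f"cell {cell_id} is not alive")
    run_lifecycle_pass(
        state,
        np.asarray([cell_id], dtype=np.int64),
        t_p_h,
        r,
        switch,
        rng,
        t_r_h=t_r_h,
    )
    return state


def run_lifecycle_pass(
    state: TumourState,
    perm: np.ndarray,
    t_p_h,
    r: int,
    switch: SwitchRule,
    rng: np.random.Generator,
    *,
    t_r_h: float,
) -> int:
    """Run the proliferation pass over ``perm`` order; returns #divisions."""
    state._ensure_capacity(perm.size)
    div_parent = np.empty(perm.size, dtype=np.int64)
    div_child = np.empty(perm.size, dtype=np.int64)
    div_phen = np.empty(perm.size, dtype=np.int8)
    div_switched = np.empty(perm.size, dtype=np.bool_)
    new_n, n_div = _kernels.lifecycle_pass(
        state.occ,
        state.pos_i,
        state.pos_j,
        state.alive,
        state.phenotype,
        state.age_h,
        state.quiescent,
        perm,
        state.n_cells,
        t_r_h,
        _t_p_array(t_p_h),
        int(r),
        float(switch.p_mut),
        switch.targets_array(),
        rng,
        div_parent,
        div_child,
        div_phen,
        div_switched,
    )
    state.n_cells = int(new_n)
    t = state.time_h
    for k in range(n_div):
        state.events.append(
            (
                t,
                "division",
                int(div_parent[k]),
                {"daughter": int(div_child[k]), "phenotype": int(div_phen[k])},
            )
        )
        if div_switched[k]:
            state.events.append((t, "switch", int(div_parent[k]), {"to": int(div_phen[k])}))
    return int(n_div)


def apply_hypoxic_death(state: TumourState, field: OxygenField) -> TumourState:
    """Kill every live cell sitting on a site with o < o_deadly.

    Dead cells vacate their site immediately (empty space for movement
    and daughters) and stop consuming oxygen.
    """
    if field.grid.shape != state.occ.shape:
        raise ValueError("oxygen field does not match the lattice")
    mask = hypoxic_mask(field)
    ids = state.live_ids()
    doomed = ids[mask[state.pos_i[ids], state.pos_j[ids]]]
    for cid in doomed:
        state.kill_cell(int(cid))
    return state
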