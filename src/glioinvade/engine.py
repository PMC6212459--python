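"""Simulation engine: initialization, the asynchronous scheduler and
replicate ensembles.

Every update interval t_r (0.8 h) the engine executes one macro-step:

1. **movement pass** — live cells are visited in a fresh uniform-random
   permutation, each running its adhesion-gated movement substeps with
   the diffusion coefficient of the current motility phase;
2. **oxygen advance** — the reaction-diffusion field is advanced by t_r
   against the current occupancy;
3. **life-cycle pass** — a second fresh permutation; each cell ages,
   divides or turns quiescent, and at the end of the pass every cell
   sitting below the lethal oxygen threshold dies.

The random permutations give every cell a different priority each
iteration.  A run ends at ``t_max`` (9 days by default) or as soon as
any cell comes within ``edge_margin`` sites of the lattice border.
All randomness flows from a single seeded generator, so ``(config,
seed)`` fully determines every output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .lifecycle import SwitchRule, apply_hypoxic_death, run_lifecycle_pass
from .model_core import LatticeGeometry, MotilityPhases, SimulationConfig, TumourState
from .morphometrics import MorphologySeries
from .motility import MoveKernel, attempt_move, build_kernel
from .oxygen import OxygenField, oxygen_advance

logger = logging.getLogger(__name__)

__all__ = [
    "initialize",
    "step",
    "run",
    "run_replicates",
    "RunResult",
    "Ensemble",
    "u87mg_config",
    "primary_config",
    "scenario_config",
    "first_death_time",
    "save_snapshot_csv",
    "save_series_csv",
    "save_events_csv",
    "save_manifest",
    "render_snapshot",
]


def initialize(config: SimulationConfig, rng: np.random.Generator) -> tuple[TumourState, OxygenField]:
    """Seed a completely filled disc of cells at the domain centre.

    Every site whose centre lies within ``initial_radius_um`` of the
    seeding centre receives a cell; phenotypes are drawn i.i.d. from the
    configured mixture and ages uniformly on [0, T_p) so division is
    desynchronised from the start.  The oxygen grid starts uniform at
    ``o_max``.
    """
    geom = config.geometry
    n = geom.n
    margin_um = config.edge_margin_sites * geom.site_um
    if config.initial_radius_um >= geom.side_mm * 1000.0 / 2.0 - margin_um:
        raise ValueError("initial radius does not fit inside the domain with its edge margin")
    state = TumourState(geom)
    ci, cj = geom.centre_site
    r_sites = int(np.floor(config.initial_radius_um / geom.site_um)) + 1
    t_p = config.t_p_table()
    phenos = np.asarray(config.phenotype_set)
    probs = config.mixture_probs()
    for i in range(max(0, ci - r_sites), min(n, ci + r_sites + 1)):
        for j in range(max(0, cj - r_sites), min(n, cj + r_sites + 1)):
            d_um = np.hypot(i - ci, j - cj) * geom.site_um
            if d_um <= config.initial_radius_um + 1e-9:
                p = int(phenos[int(rng.choice(len(phenos), p=probs))])
                age = float(rng.uniform(0.0, t_p[p]))
                state.add_cell(i, j, p, age)
    field = OxygenField(geom, config.oxygen)
    return state, field


def _switch_rule(config: SimulationConfig) -> SwitchRule:
    return SwitchRule(config.switch_probability, config.effective_switch_targets())


def step(
    state: TumourState,
    field: OxygenField,
    config: SimulationConfig,
    rng: np.random.Generator,
    kernel: MoveKernel | None = None,
) -> tuple[TumourState, OxygenField]:
    """Advance the simulation by one macro-step of ``t_r`` hours."""
    geom = config.geometry
    if kernel is None:
        kernel = build_kernel(config.motility.d_c_at(state.time_h), geom.site_um, config.t_r_h)
    live = state.live_ids()
    # (1) movement pass
    if live.size and kernel.p_move > 0.0:
        perm = rng.permutation(live)
        if config.log_moves:
            for cid in perm:
                attempt_move(state, int(cid), kernel, rng, log=True)
        else:
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
    # (2) oxygen
    oxygen_advance(field, state.occupied_mask(), config.t_r_h, method=config.oxygen_method)
    # (3) life cycle, deaths applied at the end of the pass
    live = state.live_ids()
    if live.size:
        perm = rng.permutation(live)
        run_lifecycle_pass(
            state,
            perm,
            config.t_p_h,
            config.proliferation_radius,
            _switch_rule(config),
            rng,
            t_r_h=config.t_r_h,
        )
    apply_hypoxic_death(state, field)
    state.time_h += config.t_r_h
    return state, field


def _near_edge(state: TumourState, margin: int) -> bool:
    ids = state.live_ids()
    if ids.size == 0:
        return False
    n = state.geometry.n
    pi = state.pos_i[ids]
    pj = state.pos_j[ids]
    border = min(pi.min(), pj.min(), n - 1 - pi.max(), n - 1 - pj.max())
    return bool(border < margin)


@dataclass
class RunResult:
    """One completed simulation: metric series, final state and event log."""

    config: SimulationConfig
    series: MorphologySeries
    state: TumourState
    events: list
    stop_reason: str


def run(config: SimulationConfig, progress: bool = False) -> RunResult:
    """Run one scenario to ``t_max`` or until the edge rule triggers."""
    rng = np.random.default_rng(config.seed)
    state, field = initialize(config, rng)
    series = MorphologySeries()
    series.append_state(state, config.cell_line)
    next_record = config.record_interval_h
    stop_reason = "t_max"
    kernel = None
    kernel_dc = None
    eps = 1e-9
    while state.time_h < config.t_max_h - eps:
        d_c = config.motility.d_c_at(state.time_h)
        if kernel is None or d_c != kernel_dc:
            kernel = build_kernel(d_c, config.geometry.site_um, config.t_r_h)
            kernel_dc = d_c
        step(state, field, config, rng, kernel)
        recorded = False
        if state.time_h >= next_record - eps:
            series.append_state(state, config.cell_line)
            next_record += config.record_interval_h
            recorded = True
        if progress or recorded:
            logger.info("t=%7.1f h  n_cells=%d", state.time_h, state.n_live)
        if state.n_live == 0:
            stop_reason = "extinct"
            break
        if _near_edge(state, config.edge_margin_sites):
            stop_reason = "edge"
            break
        if config.stop_at_first_death and any(e[1] == "death" for e in state.events):
            stop_reason = "first_death"
            break
    if len(series) == 0 or series.records[-1]["time_h"] < state.time_h - eps:
        if state.n_live > 0:
            series.append_state(state, config.cell_line)
    return RunResult(config, series, state, state.events, stop_reason)


@dataclass
class Ensemble:
    """Replicate ensemble with per-timepoint mean and spread of each metric."""

    results: list[RunResult]

    @property
    def n(self) -> int:
        return len(self.results)

    def frames(self) -> list[pd.DataFrame]:
        return [r.series.as_frame() for r in self.results]

    def _stacked(self, mode: str) -> pd.DataFrame:
        stacked = pd.concat(self.frames(), ignore_index=True)
        # keep the regular recording grid; the extra final-state record a
        # run appends when it stops mid-interval would otherwise add
        # one-replicate timepoints to the ensemble statistics
        interval = self.results[0].config.record_interval_h
        on_grid = np.isclose(stacked["time_h"] % interval, 0.0) | np.isclose(
            stacked["time_h"] % interval, interval
        )
        stacked = stacked[on_grid]
        if mode == "complete":
            counts = stacked.groupby("time_h")["n_cells"].count()
            common = counts[counts == self.n].index
            return stacked[stacked["time_h"].isin(common)]
        if mode == "available":
            return stacked
        raise ValueError(f"unknown mode {mode!r}")

    def mean_frame(self, mode: str = "available") -> pd.DataFrame:
        """Per-timepoint metric means across replicates.

        ``available`` (default) averages whichever replicates are still
        running at each timepoint — replicates stopped by the edge rule
        simply drop out, as in-vitro spheroids leave the analysis once
        their cells reach the well boundary.  ``complete`` keeps only
        timepoints reached by every replicate.
        """
        return self._stacked(mode).groupby("time_h", as_index=False).mean()

    def std_frame(self, mode: str = "available") -> pd.DataFrame:
        return self._stacked(mode).groupby("time_h", as_index=False).std(ddof=1)

    def replicate_counts(self) -> pd.Series:
        """Number of replicates contributing at each timepoint."""
        return pd.concat(self.frames(), ignore_index=True).groupby("time_h")["n_cells"].count()


def run_replicates(config: SimulationConfig, n: int) -> Ensemble:
    """Run ``n`` independent replicates with seeds seed+0 .. seed+n-1.

    Replicates differ only through the stochastic cell movement and the
    random initialisation of phenotypes and ages.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    results = []
    for k in range(n):
        results.append(run(config.replace(seed=config.seed + k)))
    return Ensemble(results)


def first_death_time(result: RunResult) -> float:
    """Time (h) of the first hypoxia-triggered death, NaN if none occurred."""
    for t, kind, _, _ in result.events:
        if kind == "death":
            return float(t)
    return float("nan")


# ---------------------------------------------------------------------------
# Scenario presets (benchmark parameterisations)
# ---------------------------------------------------------------------------


def u87mg_config(two_phase: bool = False, **overrides) -> SimulationConfig:
    """U87MG-like scenario: low + highly adhesive phenotypes {0, 1, 6, 7}.

    T_p = 31 h (doubling-time estimate), initial disc radius 140 um.
    Motility is either single-phase D_c = 5e-9 cm^2/s or two-phase with
    D_c1 = 1.5e-8 cm^2/s on [0, 24] h and D_c2 = 3e-9 cm^2/s after,
    matching the fast-then-slow expansion seen in vitro.
    """
    motility = (
        MotilityPhases.two_phase(1.5e-8, 3e-9) if two_phase else MotilityPhases.constant(5e-9)
    )
    base = dict(
        phenotype_set=(0, 1, 6, 7),
        t_p_h=31.0,
        initial_radius_um=140.0,
        motility=motility,
        cell_line="u87mg",
    )
    base.update(overrides)
    return SimulationConfig(**base)


def primary_config(two_phase: bool = False, **overrides) -> SimulationConfig:
    """Primary-GB-like scenario: middle + highly adhesive phenotypes {2..7}.

    T_p = 25 h, initial disc radius 200 um.  Motility is single-phase
    D_c = 2e-8 cm^2/s or two-phase with D_c1 = 4e-10 cm^2/s on [0, 24] h
    and D_c2 = 4e-8 cm^2/s after (slow start, faster linear expansion).
    """
    motility = (
        MotilityPhases.two_phase(4e-10, 4e-8) if two_phase else MotilityPhases.constant(2e-8)
    )
    base = dict(
        phenotype_set=(2, 3, 4, 5, 6, 7),
        t_p_h=25.0,
        initial_radius_um=200.0,
        motility=motility,
        cell_line="primary",
    )
    base.update(overrides)
    return SimulationConfig(**base)


def scenario_config(name: str, two_phase: bool = False, **overrides) -> SimulationConfig:
    if name == "u87mg":
        return u87mg_config(two_phase, **overrides)
    if name == "primary":
        return primary_config(two_phase, **overrides)
    raise ValueError(f"unknown scenario {name!r} (expected 'u87mg' or 'primary')")


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------


def save_snapshot_csv(state: TumourState, path) -> None:
    """Write the phenotype grid (adhesion value per site, -1 empty) as CSV."""
    np.savetxt(path, state.phenotype_grid(), fmt="%d", delimiter=",")


def save_series_csv(series: MorphologySeries | pd.DataFrame, path) -> None:
    frame = series.as_frame() if isinstance(series, MorphologySeries) else series
    frame.to_csv(path, index=False)


def save_events_csv(events: list, path) -> None:
    rows = [
        {"time_h": t, "event": kind, "cell_id": cid, "details": repr(details)}
        for t, kind, cid, details in events
    ]
    pd.DataFrame(rows, columns=["time_h", "event", "cell_id", "details"]).to_csv(path, index=False)


def save_manifest(config: SimulationConfig, path) -> None:
    import glioinvade

    manifest = {"glioinvade_version": glioinvade.__version__, "config": config.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def render_snapshot(state: TumourState, path, dpi: int = 150) -> None:
    """Render the lattice, colour-coded by adhesion value 0 (blue) .. 7 (red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colors

    grid = state.phenotype_grid().astype(float)
    grid[grid < 0] = np.nan
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad("white")
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(grid.T, origin="lower", cmap=cmap, norm=colors.Normalize(0, 7))
    ax.set_title(f"t = {state.time_h:.0f} h, {state.n_live} cells")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="adhesion preference")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
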