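"""Core domain types for the spheroid invasion model.

The model is a hybrid discrete–continuum cellular automaton: individual
tumour cells live on a 2D square lattice (one cell per site) and interact
with a continuous oxygen field.  Every cell carries an *adhesion
preference* — an integer in [0, 7] giving the number of occupied Moore
neighbours the cell requires at a destination site before it will move
there.  Heterogeneity in this single trait is the model's driver of the
distinct invasion morphologies (starburst vs cohesive sheet-like).

This module holds the shared containers: the lattice geometry, the
tumour state (occupancy grid + cell registry + event log, kept mutually
consistent), motility phases and the full simulation configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "N_PHENOTYPES",
    "PhenotypeError",
    "category",
    "LatticeGeometry",
    "CellState",
    "MotilityPhases",
    "TumourState",
    "SimulationConfig",
    "audit_consistency",
]

#: Adhesion preference values run from 0 (prefers empty surroundings) to 7
#: (prefers a fully populated Moore neighbourhood).
N_PHENOTYPES = 8

EMPTY = -1  # occupancy-grid marker for an unoccupied site


class PhenotypeError(ValueError):
    """Raised for adhesion-preference values outside [0, 7]."""


def validate_phenotype(p: int) -> int:
    if not (0 <= int(p) <= 7) or int(p) != p:
        raise PhenotypeError(f"adhesion preference must be an integer in [0, 7], got {p!r}")
    return int(p)


def category(phenotype: int) -> str:
    """Adhesion class of a phenotype: ``low`` {0,1}, ``middle`` {2..5}, ``high`` {6,7}.

    Low-adhesive cells prefer empty neighbourhoods and migrate as single
    cells; highly adhesive cells are attracted to densely populated
    neighbourhoods and form the immotile maternal core.
    """
    p = validate_phenotype(phenotype)
    if p <= 1:
        return "low"
    if p <= 5:
        return "middle"
    return "high"


@dataclass(frozen=True)
class LatticeGeometry:
    """Square simulation domain.

    Parameters
    ----------
    side_mm:
        Physical side length L of the domain in millimetres.
    site_um:
        Lattice spacing h in micrometres; each h x h site holds at most
        one cell.
    """

    side_mm: float = 5.0
    site_um: float = 20.0

    @property
    def n(self) -> int:
        """Number of sites per side (250 for the default 5 mm / 20 um)."""
        return int(round(self.side_mm * 1000.0 / self.site_um))

    @property
    def centre_site(self) -> tuple[int, int]:
        """The lattice site taken as the spheroid seeding centre."""
        return (self.n // 2, self.n // 2)

    def site_centre_um(self, i, j):
        """Physical position of site centres, ((i+0.5)h, (j+0.5)h) in um."""
        h = self.site_um
        return ((np.asarray(i) + 0.5) * h, (np.asarray(j) + 0.5) * h)

    def distance_from_centre_um(self, i, j):
        """Euclidean distance (um) from site centres to the seeding centre."""
        ci, cj = self.centre_site
        di = (np.asarray(i, dtype=float) - ci) * self.site_um
        dj = (np.asarray(j, dtype=float) - cj) * self.site_um
        return np.hypot(di, dj)


@dataclass
class CellState:
    """Read-only snapshot of a single cell (the registry itself is array-backed)."""

    cell_id: int
    position: tuple[int, int]
    phenotype: int
    age_h: float
    quiescent: bool
    alive: bool


@dataclass(frozen=True)
class MotilityPhases:
    """Piecewise-constant cell diffusion coefficient over time.

    ``phases`` is an ordered sequence of ``(t_start_h, t_end_h, D_c_cm2_s)``
    intervals that partition [0, t_max) without overlap.  Two-phase
    kinetics (a distinct motility before and after 24 h) reproduce the
    different early/late expansion speeds seen in the spheroid assay.
    """

    phases: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        prev_end = 0.0
        for t0, t1, dc in self.phases:
            if dc < 0:
                raise ValueError("diffusion coefficient must be >= 0")
            if t0 != prev_end:
                raise ValueError("motility phases must partition [0, t_max) contiguously")
            if not (t1 > t0):
                raise ValueError("phase end must exceed phase start")
            prev_end = t1

    @classmethod
    def constant(cls, d_c: float, t_max_h: float = np.inf) -> "MotilityPhases":
        return cls(((0.0, float(t_max_h), float(d_c)),))

    @classmethod
    def two_phase(cls, d_c1: float, d_c2: float, t_switch_h: float = 24.0) -> "MotilityPhases":
        return cls(((0.0, float(t_switch_h), float(d_c1)), (float(t_switch_h), np.inf, float(d_c2))))

    def d_c_at(self, t_h: float) -> float:
        """Diffusion coefficient (cm^2/s) in force at simulation time t."""
        for t0, t1, dc in self.phases:
            if t0 <= t_h < t1:
                return dc
        return self.phases[-1][2]


class TumourState:
    """Lattice occupancy + cell registry + event log, kept mutually consistent.

    The occupancy grid stores, per site, the id of the live cell sitting
    there (or -1).  The registry is a structure of arrays indexed by cell
    id; ids are allocated monotonically and never reused, so the event
    log identifies every cell unambiguously.  Dead cells keep their
    registry row (``alive=False``) but vacate their site: dead cells are
    treated as empty space.
    """

    def __init__(self, geometry: LatticeGeometry):
        self.geometry = geometry
        n = geometry.n
        self.occ = np.full((n, n), EMPTY, dtype=np.int32)
        self.time_h = 0.0
        cap = 1024
        self.pos_i = np.zeros(cap, dtype=np.int32)
        self.pos_j = np.zeros(cap, dtype=np.int32)
        self.phenotype = np.zeros(cap, dtype=np.int8)
        self.age_h = np.zeros(cap, dtype=np.float64)
        self.quiescent = np.zeros(cap, dtype=np.bool_)
        self.alive = np.zeros(cap, dtype=np.bool_)
        self.n_cells = 0  # total ids ever allocated
        self.events: list[tuple] = []  # (time_h, kind, cell_id, details)

    # -- registry management -------------------------------------------------

    def _ensure_capacity(self, extra: int) -> None:
        need = self.n_cells + extra
        cap = len(self.pos_i)
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        for name in ("pos_i", "pos_j", "phenotype", "age_h", "quiescent", "alive"):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=old.dtype)
            new[: self.n_cells] = old[: self.n_cells]
            setattr(self, name, new)

    def add_cell(self, i: int, j: int, phenotype: int, age_h: float = 0.0, *, log: bool = False) -> int:
        """Place a new cell on an empty site and return its id."""
        if self.occ[i, j] != EMPTY:
            raise ValueError(f"site ({i}, {j}) is already occupied")
        validate_phenotype(phenotype)
        self._ensure_capacity(1)
        cid = self.n_cells
        self.pos_i[cid] = i
        self.pos_j[cid] = j
        self.phenotype[cid] = phenotype
        self.age_h[cid] = age_h
        self.quiescent[cid] = False
        self.alive[cid] = True
        self.occ[i, j] = cid
        self.n_cells += 1
        if log:
            self.events.append((self.time_h, "division", cid, {"site": (i, j)}))
        return cid

    def kill_cell(self, cid: int, *, log: bool = True) -> None:
        if not self.alive[cid]:
            return
        self.occ[self.pos_i[cid], self.pos_j[cid]] = EMPTY
        self.alive[cid] = False
        if log:
            self.events.append((self.time_h, "death", int(cid), {}))

    # -- views ---------------------------------------------------------------

    @property
    def n_live(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n_cells]))

    def live_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self.n_cells]).astype(np.int64)

    def live_positions(self) -> tuple[np.ndarray, np.ndarray]:
        ids = self.live_ids()
        return self.pos_i[ids], self.pos_j[ids]

    def occupied_mask(self) -> np.ndarray:
        """Boolean grid of sites holding a live cell."""
        return self.occ != EMPTY

    def phenotype_grid(self) -> np.ndarray:
        """Integer grid: adhesion preference per site, -1 where empty."""
        grid = np.full(self.occ.shape, -1, dtype=np.int8)
        mask = self.occ != EMPTY
        grid[mask] = self.phenotype[self.occ[mask]]
        return grid

    def cell(self, cid: int) -> CellState:
        return CellState(
            cell_id=int(cid),
            position=(int(self.pos_i[cid]), int(self.pos_j[cid])),
            phenotype=int(self.phenotype[cid]),
            age_h=float(self.age_h[cid]),
            quiescent=bool(self.quiescent[cid]),
            alive=bool(self.alive[cid]),
        )

    def event_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, kind, _, _ in self.events:
            counts[kind] = counts.get(kind, 0) + 1
        return counts


def audit_consistency(state: TumourState) -> bool:
    """Check the occupancy <-> registry bijection.

    True iff every live cell occupies exactly the site the grid says it
    does, every occupied site points back at a live cell, and the number
    of occupied sites equals the number of live cells (single occupancy).
    """
    occ = state.occ
    n_occ = int(np.count_nonzero(occ != EMPTY))
    live = state.live_ids()
    if n_occ != live.size:
        return False
    for cid in live:
        i, j = state.pos_i[cid], state.pos_j[cid]
        if occ[i, j] != cid:
            return False
    referenced = occ[occ != EMPTY]
    if referenced.size and not state.alive[referenced].all():
        return False
    return True


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class OxygenParams:
    """Oxygen field parameters (see :mod:`glioinvade.oxygen` for the PDE).

    Concentration is normalised so the medium (domain boundary) sits at
    ``o_max = 1``.  ``gamma_o`` is the per-cell consumption rate; its
    default was calibrated once so that, in the primary-cell scenario,
    the first hypoxia-triggered death appears near 150 h of growth.
    """

    d_o_cm2_s: float = 1e-5
    alpha_o_per_s: float = 0.0
    gamma_o_per_s: float = 0.012
    o_max: float = 1.0
    o_deadly: float = 0.1

    def __post_init__(self):
        if self.d_o_cm2_s <= 0:
            raise ValueError("oxygen diffusion coefficient must be > 0")
        if self.alpha_o_per_s < 0 or self.gamma_o_per_s < 0:
            raise ValueError("decay and consumption rates must be >= 0")
        if not (0 <= self.o_deadly < self.o_max):
            raise ValueError("require 0 <= o_deadly < o_max")


@dataclass
class SimulationConfig:
    """Full parameterisation of one in-silico spheroid scenario.

    Defaults mirror the benchmark conditions: 5 mm domain at 20 um
    resolution, 0.8 h update interval, 9-day horizon, runs stopping when
    any cell comes within 5 sites of the domain edge.
    """

    geometry: LatticeGeometry = field(default_factory=LatticeGeometry)
    t_r_h: float = 0.8
    #: proliferation age per phenotype (hours); a scalar applies to all.
    t_p_h: float | Mapping[int, float] = 31.0
    motility: MotilityPhases = field(default_factory=lambda: MotilityPhases.constant(5e-9))
    phenotype_set: tuple[int, ...] = (0, 1, 6, 7)
    #: sampling probabilities for the initial phenotype draw, aligned with
    #: phenotype_set; None means uniform.
    initial_mixture: tuple[float, ...] | None = None
    initial_radius_um: float = 140.0
    switch_probability: float = 0.0
    #: phenotypes a mitotic switch may select from; None = phenotype_set.
    switch_targets: tuple[int, ...] | None = None
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    t_max_h: float = 216.0
    edge_margin_sites: int = 5
    seed: int = 0
    proliferation_radius: int = 2
    record_interval_h: float = 8.0
    oxygen_method: str = "auto"
    log_moves: bool = False
    stop_at_first_death: bool = False
    #: which core-radius definition applies: "u87mg" (connectivity-based
    #: maternal core) or "primary" (not separable from the invasive area).
    cell_line: str = "u87mg"

    def __post_init__(self):
        if self.t_r_h <= 0:
            raise ValueError("update interval t_r must be > 0")
        self.phenotype_set = tuple(validate_phenotype(p) for p in self.phenotype_set)
        if not self.phenotype_set:
            raise ValueError("phenotype_set must be non-empty")
        if self.initial_mixture is not None:
            mix = np.asarray(self.initial_mixture, dtype=float)
            if mix.size != len(self.phenotype_set):
                raise ValueError("initial_mixture length must match phenotype_set")
            if (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
                raise ValueError("initial_mixture must be a probability vector")
            self.initial_mixture = tuple(float(x) for x in mix)
        if not (0.0 <= self.switch_probability <= 1.0):
            raise ValueError("switch probability must lie in [0, 1]")
        if self.switch_targets is not None:
            self.switch_targets = tuple(validate_phenotype(p) for p in self.switch_targets)
            if not self.switch_targets:
                raise ValueError("switch_targets must be non-empty")
        if self.initial_radius_um >= self.geometry.side_mm * 1000.0 / 2.0:
            raise ValueError("initial radius must fit inside the domain")
        for p, tp in self.t_p_table().items():
            if tp <= 0:
                raise ValueError("proliferation times must be > 0")

    def t_p_table(self) -> dict[int, float]:
        """Proliferation age (h) per phenotype value 0..7."""
        if isinstance(self.t_p_h, Mapping):
            table = {p: float(self.t_p_h.get(p, np.inf)) for p in range(N_PHENOTYPES)}
            for p in self.phenotype_set:
                if p not in self.t_p_h:
                    raise ValueError(f"t_p_h mapping lacks phenotype {p}")
            return table
        return {p: float(self.t_p_h) for p in range(N_PHENOTYPES)}

    def mixture_probs(self) -> np.ndarray:
        if self.initial_mixture is None:
            return np.full(len(self.phenotype_set), 1.0 / len(self.phenotype_set))
        return np.asarray(self.initial_mixture, dtype=float)

    def effective_switch_targets(self) -> tuple[int, ...]:
        return self.switch_targets if self.switch_targets is not None else self.phenotype_set

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            # geometry
            "lattice_side_mm": self.geometry.side_mm,
            "site_size_um": self.geometry.site_um,
            # kinetics (hours / cm^2 s^-1)
            "update_interval_h": self.t_r_h,
            "proliferation_time_h": dict(self.t_p_h) if isinstance(self.t_p_h, Mapping) else self.t_p_h,
            "motility_phases_cm2_s": [
                [t0, None if np.isinf(t1) else t1, dc] for t0, t1, dc in self.motility.phases
            ],
            # phenotype mixture
            "phenotype_set": list(self.phenotype_set),
            "initial_mixture": None if self.initial_mixture is None else list(self.initial_mixture),
            "initial_radius_um": self.initial_radius_um,
            "switch_probability": self.switch_probability,
            "switch_targets": None if self.switch_targets is None else list(self.switch_targets),
            # oxygen (cm^2/s, 1/s, normalised concentration)
            "oxygen_diffusion_cm2_s": self.oxygen.d_o_cm2_s,
            "oxygen_decay_per_s": self.oxygen.alpha_o_per_s,
            "oxygen_consumption_per_s": self.oxygen.gamma_o_per_s,
            "oxygen_max": self.oxygen.o_max,
            "oxygen_deadly": self.oxygen.o_deadly,
            # run control
            "t_max_h": self.t_max_h,
            "edge_margin_sites": self.edge_margin_sites,
            "seed": self.seed,
            "proliferation_radius_sites": self.proliferation_radius,
            "record_interval_h": self.record_interval_h,
            "oxygen_method": self.oxygen_method,
            "log_moves": self.log_moves,
            "stop_at_first_death": self.stop_at_first_death,
            "cell_line": self.cell_line,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        phases = tuple(
            (float(t0), np.inf if t1 is None else float(t1), float(dc))
            for t0, t1, dc in d["motility_phases_cm2_s"]
        )
        tp = d["proliferation_time_h"]
        if isinstance(tp, Mapping):
            tp = {int(k): float(v) for k, v in tp.items()}
        return cls(
            geometry=LatticeGeometry(side_mm=d["lattice_side_mm"], site_um=d["site_size_um"]),
            t_r_h=d["update_interval_h"],
            t_p_h=tp,
            motility=MotilityPhases(phases),
            phenotype_set=tuple(d["phenotype_set"]),
            initial_mixture=None if d.get("initial_mixture") is None else tuple(d["initial_mixture"]),
            initial_radius_um=d["initial_radius_um"],
            switch_probability=d.get("switch_probability", 0.0),
            switch_targets=None if d.get("switch_targets") is None else tuple(d["switch_targets"]),
            oxygen=OxygenParams(
                d_o_cm2_s=d["oxygen_diffusion_cm2_s"],
                alpha_o_per_s=d["oxygen_decay_per_s"],
                gamma_o_per_s=d["oxygen_consumption_per_s"],
                o_max=d["oxygen_max"],
                o_deadly=d["oxygen_deadly"],
            ),
            t_max_h=d["t_max_h"],
            edge_margin_sites=d["edge_margin_sites"],
            seed=d.get("seed", 0),
            proliferation_radius=d.get("proliferation_radius_sites", 2),
            record_interval_h=d.get("record_interval_h", 8.0),
            oxygen_method=d.get("oxygen_method", "auto"),
            log_moves=d.get("log_moves", False),
            stop_at_first_death=d.get("stop_at_first_death", False),
            cell_line=d.get("cell_line", "u87mg"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)
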