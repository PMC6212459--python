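"""Morphometrics of simulated spheroids.

Mirrors the image-analysis pipeline used on brightfield micrographs of
the invasion assay, applied to lattice occupancy states:

* **invasive radius** — the maximum radius, taken from the seeding
  centre, that encloses all tumour cells;
* **core radius** — the extent of the cohesive maternal spheroid.  For
  the U87MG-like morphology the core is the 8-connected component
  around the centre; for the primary-like morphology core and invasive
  area cannot be separated (the whole tumour is one cohesive mass), so
  the metric is reported as missing;
* **invasive rim** — invasive radius minus core radius;
* **compactness** — mean fraction of occupied Moore neighbours per
  cell, in [0, 1]; 1 for the interior of a packed block;
* **sparseness** — mean nearest-neighbour distance between cells in
  units of the lattice spacing; 1 for a packed block, growing as cells
  scatter;
* **expansion speed** — ordinary-least-squares slope of an
  ensemble-mean radius against time over a stated window (um/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .model_core import TumourState

__all__ = [
    "MetricUndefinedError",
    "MorphologySeries",
    "invasive_radius",
    "core_radius",
    "compactness",
    "sparseness",
    "phenotype_frequencies",
    "largest_component_fraction",
    "snapshot_metrics",
    "expansion_speed",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class MetricUndefinedError(ValueError):
    """A metric was requested on a state where it is undefined."""


def _require_live(state: TumourState, minimum: int = 1) -> np.ndarray:
    ids = state.live_ids()
    if ids.size < minimum:
        raise MetricUndefinedError(f"metric needs >= {minimum} live cells, found {ids.size}")
    return ids


def invasive_radius(state: TumourState) -> float:
    """Maximum distance (um) from the seeding centre enclosing all cells."""
    ids = _require_live(state)
    d = state.geometry.distance_from_centre_um(state.pos_i[ids], state.pos_j[ids])
    return float(d.max())


def core_radius(state: TumourState, cell_line: str = "u87mg") -> float:
    """Radius (um) of the cohesive maternal core.

    ``u87mg`` — maximum centre distance within the 8-connected occupied
    component containing the centre-most cell.  ``primary`` — returns
    NaN: the cohesive morphology offers no phenotype- or
    connectivity-based core/invasive separation, so the analysis tracks
    the invasive radius only.
    """
    if cell_line == "primary":
        _require_live(state)
        return float("nan")
    if cell_line != "u87mg":
        raise ValueError(f"unknown cell line {cell_line!r}")
    ids = _require_live(state)
    occupied = state.occupied_mask()
    labels, _ = ndimage.label(occupied, structure=_EIGHT_CONNECTED)
    d = state.geometry.distance_from_centre_um(state.pos_i[ids], state.pos_j[ids])
    seed = ids[np.argmin(d)]  # occupied cell nearest the seeding centre
    core_label = labels[state.pos_i[seed], state.pos_j[seed]]
    in_core = labels[state.pos_i[ids], state.pos_j[ids]] == core_label
    return float(d[in_core].max())


def compactness(state: TumourState) -> float:
    """Mean occupied-Moore-neighbour fraction per live cell, in [0, 1]."""
    ids = _require_live(state)
    occupied = state.occupied_mask().astype(np.int16)
    kernel = np.ones((3, 3), dtype=np.int16)
    kernel[1, 1] = 0
    counts = ndimage.convolve(occupied, kernel, mode="constant", cval=0)
    per_cell = counts[state.pos_i[ids], state.pos_j[ids]]
    return float(per_cell.mean() / 8.0)


def sparseness(state: TumourState) -> float:
    """Mean nearest-other-cell distance in units of the lattice spacing."""
    ids = _require_live(state, minimum=2)
    pts = np.column_stack([state.pos_i[ids], state.pos_j[ids]]).astype(float)
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return float(dist[:, 1].mean())


def phenotype_frequencies(state: TumourState) -> np.ndarray:
    """Relative frequency of each adhesion value 0..7 among live cells."""
    ids = _require_live(state)
    counts = np.bincount(state.phenotype[ids].astype(np.int64), minlength=8)
    return counts / counts.sum()


def largest_component_fraction(state: TumourState) -> float:
    """Fraction of live cells in the largest 8-connected component.

    Close to 1 for the cohesive, sheet-like morphology; well below 1
    for the non-cohesive starburst morphology where single cells detach.
    """
    ids = _require_live(state)
    occupied = state.occupied_mask()
    labels, n_lab = ndimage.label(occupied, structure=_EIGHT_CONNECTED)
    if n_lab == 0:
        return 0.0
    sizes = np.bincount(labels.ravel())[1:]
    return float(sizes.max() / ids.size)


def snapshot_metrics(state: TumourState, cell_line: str = "u87mg") -> dict:
    """All per-timepoint metrics for one state, as a flat record."""
    inv = invasive_radius(state)
    core = core_radius(state, cell_line)
    rec = {
        "time_h": state.time_h,
        "n_cells": state.n_live,
        "core_radius_um": core,
        "invasive_radius_um": inv,
        "invasive_rim_um": inv - core if np.isfinite(core) else float("nan"),
        "compactness": compactness(state),
        "sparseness": sparseness(state) if state.n_live >= 2 else float("nan"),
        "largest_component_fraction": largest_component_fraction(state),
    }
    freqs = phenotype_frequencies(state)
    for p in range(8):
        rec[f"freq_phenotype_{p}"] = float(freqs[p])
    return rec


@dataclass
class MorphologySeries:
    """Per-timepoint morphology records of one run (or an ensemble mean)."""

    records: list[dict] = field(default_factory=list)

    def append_state(self, state: TumourState, cell_line: str = "u87mg") -> None:
        self.records.append(snapshot_metrics(state, cell_line))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray([r["time_h"] for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


def expansion_speed(series, window: tuple[float, float], metric: str = "invasive_radius_um") -> float:
    """OLS slope (um/h) of a radius-vs-time series restricted to ``window``.

    ``series`` is a :class:`MorphologySeries` or a DataFrame with a
    ``time_h`` column (typically the ensemble mean over replicates).
    """
    frame = series.as_frame() if isinstance(series, MorphologySeries) else series
    t0, t1 = window
    sel = frame[(frame["time_h"] >= t0) & (frame["time_h"] <= t1)]
    sel = sel.dropna(subset=[metric])
    if len(sel) < 2:
        raise MetricUndefinedError("expansion speed needs >= 2 timepoints in the window")
    fit = stats.linregress(sel["time_h"].to_numpy(), sel[metric].to_numpy())
    return float(fit.slope)
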