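"""Canned in-silico studies on top of the engine.

* :func:`mixture_panel` — the morphology spectrum obtained by combining
  phenotypes of different adhesion preference at fixed proliferation
  and motility rates;
* :func:`trend_study` — directional effect of doubling the
  proliferation or motility rate (or enabling the mitotic switch) on
  population, invasive radius, compactness and sparseness, assessed
  with paired-seed one-sided tests;
* :func:`switch_study` — paired switch-on/switch-off ensembles showing
  phenotype-frequency flattening and, for the primary scenario, the
  reduced population and expansion caused by random switching;
* :func:`necrosis_onset` / :func:`calibrate_gamma_o` — first
  hypoxia-triggered death times, and the documented one-off calibration
  of the oxygen consumption rate against the observed necrosis onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import Ensemble, RunResult, first_death_time, run, run_replicates, scenario_config
from .model_core import SimulationConfig
from .morphometrics import snapshot_metrics

__all__ = [
    "mixture_panel",
    "trend_study",
    "switch_study",
    "necrosis_onset",
    "calibrate_gamma_o",
    "PanelEntry",
    "TrendReport",
    "SwitchReport",
]

METRICS = ("n_cells", "invasive_radius_um", "compactness", "sparseness")


# ---------------------------------------------------------------------------
# Morphology panel
# ---------------------------------------------------------------------------


@dataclass
class PanelEntry:
    phenotype_set: tuple[int, ...]
    result: RunResult
    final_metrics: dict


def mixture_panel(
    base_config: SimulationConfig,
    mixtures: list[tuple[int, ...]],
    seed: int | None = None,
) -> list[PanelEntry]:
    """One run per phenotype mixture, all other rates held fixed.

    The classic panel uses T_p = 31 h and D_c = 5e-9 cm^2/s for every
    mixture (the defaults of the U87MG single-phase preset), so the
    morphology differences are attributable to adhesion alone.
    """
    if not mixtures:
        raise ValueError("need at least one phenotype mixture")
    entries = []
    for mix in mixtures:
        cfg = base_config.replace(
            phenotype_set=tuple(mix),
            initial_mixture=None,
            switch_targets=None,
            seed=base_config.seed if seed is None else seed,
        )
        res = run(cfg)
        entries.append(PanelEntry(tuple(mix), res, snapshot_metrics(res.state, cfg.cell_line)))
    return entries


# ---------------------------------------------------------------------------
# Table-1-style trend study
# ---------------------------------------------------------------------------


def _perturb(config: SimulationConfig, factor: str, multiplier: float) -> SimulationConfig:
    if factor == "proliferation":
        # rate up = proliferation time down
        if isinstance(config.t_p_h, dict):
            tp = {p: v / multiplier for p, v in config.t_p_h.items()}
        else:
            tp = config.t_p_h / multiplier
        return config.replace(t_p_h=tp)
    if factor == "motility":
        phases = tuple((t0, t1, dc * multiplier) for t0, t1, dc in config.motility.phases)
        return config.replace(motility=type(config.motility)(phases))
    if factor == "switch":
        return config.replace(switch_probability=0.5)
    raise ValueError(f"unknown factor {factor!r}")


def _final_common_metrics(ens_a: Ensemble, ens_b: Ensemble) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """Latest timepoint reached by every run of both arms, plus per-run metrics there."""
    frames = ens_a.frames() + ens_b.frames()
    common = set(frames[0]["time_h"])
    for f in frames[1:]:
        common &= set(f["time_h"])
    if not common:
        raise RuntimeError("replicate arms share no common timepoint")
    t_star = max(common)

    def at_t(ens):
        rows = [f.loc[f["time_h"] == t_star].iloc[0] for f in ens.frames()]
        return pd.DataFrame(rows).reset_index(drop=True)

    return t_star, at_t(ens_a), at_t(ens_b)


@dataclass
class TrendReport:
    """Directional outcome of one rate perturbation.

    ``arrows`` maps each metric to "up", "down" or "flat" (one-sided
    Wilcoxon signed-rank on paired-seed differences at level ``alpha``).
    """

    factor: str
    multiplier: float
    time_h: float
    arrows: dict[str, str]
    p_values: dict[str, tuple[float, float]]
    baseline_means: dict[str, float]
    perturbed_means: dict[str, float]
    freq_shift: dict[int, float]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "metric": m,
                "baseline": self.baseline_means[m],
                "perturbed": self.perturbed_means[m],
                "direction": self.arrows[m],
                "p_up": self.p_values[m][0],
                "p_down": self.p_values[m][1],
            }
            for m in METRICS
        ]
        return pd.DataFrame(rows)


def trend_study(
    base_config: SimulationConfig,
    factor: str,
    n_reps: int = 10,
    multiplier: float = 2.0,
    alpha: float = 0.05,
) -> TrendReport:
    """Effect of increasing one rate, with common random numbers.

    Both arms reuse the same replicate seeds so the paired differences
    isolate the perturbation from Monte-Carlo noise.
    """
    base = run_replicates(base_config, n_reps)
    pert = run_replicates(_perturb(base_config, factor, multiplier), n_reps)
    t_star, a, b = _final_common_metrics(base, pert)
    arrows: dict[str, str] = {}
    pvals: dict[str, tuple[float, float]] = {}
    for m in METRICS:
        diff = b[m].to_numpy(dtype=float) - a[m].to_numpy(dtype=float)
        if np.allclose(diff, 0.0):
            p_up = p_down = 1.0
        else:
            p_up = stats.wilcoxon(diff, alternative="greater").pvalue
            p_down = stats.wilcoxon(diff, alternative="less").pvalue
        pvals[m] = (float(p_up), float(p_down))
        arrows[m] = "up" if p_up < alpha else ("down" if p_down < alpha else "flat")
    freq_shift = {}
    for p in range(8):
        col = f"freq_phenotype_{p}"
        freq_shift[p] = float(b[col].mean() - a[col].mean())
    return TrendReport(
        factor=factor,
        multiplier=multiplier,
        time_h=float(t_star),
        arrows=arrows,
        p_values=pvals,
        baseline_means={m: float(a[m].mean()) for m in METRICS},
        perturbed_means={m: float(b[m].mean()) for m in METRICS},
        freq_shift=freq_shift,
    )


# ---------------------------------------------------------------------------
# Phenotypic-switch study
# ---------------------------------------------------------------------------


@dataclass
class SwitchReport:
    scenario: str
    time_h: float
    off_means: dict[str, float]
    on_means: dict[str, float]
    on_final_freqs: np.ndarray
    max_freq_deviation: float  # from uniform over the allowed set, switch-on arm

    def population_decreased(self) -> bool:
        return self.on_means["n_cells"] < self.off_means["n_cells"]

    def expansion_decreased(self) -> bool:
        return self.on_means["invasive_radius_um"] < self.off_means["invasive_radius_um"]


def switch_study(
    scenario: str,
    p_mut: float = 0.5,
    n_reps: int = 10,
    base_config: SimulationConfig | None = None,
) -> SwitchReport:
    """Paired ensembles with the mitotic phenotype switch off vs on."""
    cfg = base_config if base_config is not None else scenario_config(scenario)
    off = run_replicates(cfg.replace(switch_probability=0.0), n_reps)
    on = run_replicates(cfg.replace(switch_probability=p_mut), n_reps)
    t_star, a, b = _final_common_metrics(off, on)
    allowed = cfg.effective_switch_targets()
    freq_cols = [f"freq_phenotype_{p}" for p in range(8)]
    on_freqs = b[freq_cols].mean().to_numpy()
    uniform = 1.0 / len(allowed)
    max_dev = max(abs(on_freqs[p] - uniform) for p in allowed)
    return SwitchReport(
        scenario=scenario,
        time_h=float(t_star),
        off_means={m: float(a[m].mean()) for m in METRICS},
        on_means={m: float(b[m].mean()) for m in METRICS},
        on_final_freqs=on_freqs,
        max_freq_deviation=float(max_dev),
    )


# ---------------------------------------------------------------------------
# Necrosis onset and the gamma_o calibration
# ---------------------------------------------------------------------------


def necrosis_onset(config: SimulationConfig, n_reps: int = 10) -> tuple[float, np.ndarray]:
    """Median (and per-replicate) time of the first hypoxia death.

    Runs stop at the first death to save work; replicates in which no
    cell dies before the run ends contribute NaN.
    """
    cfg = config.replace(stop_at_first_death=True)
    ens = run_replicates(cfg, n_reps)
    times = np.asarray([first_death_time(r) for r in ens.results])
    return float(np.nanmedian(times)), times


def calibrate_gamma_o(
    config: SimulationConfig,
    target_h: float = 150.0,
    n_reps: int = 3,
    lo: float = 5e-3,
    hi: float = 0.3,
    iters: int = 12,
) -> float:
    """Bisection of the per-cell oxygen consumption rate gamma_o.

    Once oxygen is normalised (o_max = 1) and decay neglected, gamma_o
    is the single free oxygen parameter; this pins it to the observable
    onset of necrosis (median first-death time ~= ``target_h`` in the
    given scenario).  Larger gamma_o makes the hypoxic centre appear
    earlier, so the onset time is monotone decreasing in gamma_o and
    bisection applies.  Used once to fix the package default.
    """

    def onset(gamma: float) -> float:
        cfg = config.replace(oxygen=config.oxygen.__class__(
            d_o_cm2_s=config.oxygen.d_o_cm2_s,
            alpha_o_per_s=config.oxygen.alpha_o_per_s,
            gamma_o_per_s=gamma,
            o_max=config.oxygen.o_max,
            o_deadly=config.oxygen.o_deadly,
        ))
        med, _ = necrosis_onset(cfg, n_reps)
        return med if np.isfinite(med) else np.inf

    for _ in range(iters):
        mid = float(np.sqrt(lo * hi))  # geometric bisection: rate spans decades
        if onset(mid) > target_h:
            lo = mid  # death too late -> consume more
        else:
            hi = mid
        if hi / lo < 1.02:
            break
    return float(np.sqrt(lo * hi))
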