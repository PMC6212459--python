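"""Morphometrics against brute-force oracles and exact geometry."""

import numpy as np
import pandas as pd
import pytest

import glioinvade as gi
from glioinvade.model_core import LatticeGeometry, TumourState
from glioinvade.morphometrics import (
    MetricUndefinedError,
    compactness,
    core_radius,
    expansion_speed,
    invasive_radius,
    largest_component_fraction,
    phenotype_frequencies,
    sparseness,
)

from conftest import place

H = 20.0


def scattered_state(rng, n_cells=60, n_side=40):
    state = TumourState(LatticeGeometry(side_mm=n_side * H / 1000.0, site_um=H))
    chosen = rng.choice(n_side * n_side, size=n_cells, replace=False)
    for k in chosen:
        state.add_cell(int(k // n_side), int(k % n_side), int(rng.integers(0, 8)))
    return state


class TestInvasiveRadius:
    def test_single_centre_cell_is_zero(self, small_state):
        ci, cj = small_state.geometry.centre_site
        small_state.add_cell(ci, cj, 0)
        assert invasive_radius(small_state) == 0.0

    def test_filled_disc_radius(self):
        state, _ = gi.make_disc(140.0)
        assert invasive_radius(state) == pytest.approx(140.0, abs=H / 2)

    def test_matches_brute_force_enumeration(self, rng):
        state = scattered_state(rng)
        ci, cj = state.geometry.centre_site
        ids = state.live_ids()
        oracle = max(
            np.hypot(int(state.pos_i[k]) - ci, int(state.pos_j[k]) - cj) * H for k in ids
        )
        assert invasive_radius(state) == pytest.approx(oracle)

    def test_empty_tumour_is_undefined(self, small_state):
        with pytest.raises(MetricUndefinedError):
            invasive_radius(small_state)

    def test_monotone_under_farther_cell(self):
        state, _ = gi.make_disc(100.0)
        before = invasive_radius(state)
        ci, cj = state.geometry.centre_site
        state.add_cell(ci + 30, cj, 0)
        assert invasive_radius(state) == pytest.approx(600.0)
        assert invasive_radius(state) > before


class TestCoreRadius:
    def test_intact_disc_core_equals_invasive(self):
        state, _ = gi.make_disc(140.0)
        assert core_radius(state, "u87mg") == invasive_radius(state)

    def test_detached_cell_grows_invasive_not_core(self):
        state, _ = gi.make_disc(140.0)
        ci, cj = state.geometry.centre_site
        state.add_cell(ci + 40, cj, 0)
        assert core_radius(state, "u87mg") == pytest.approx(140.0, abs=H / 2)
        assert invasive_radius(state) == pytest.approx(800.0)

    def test_primary_core_is_not_separable(self):
        state, _ = gi.make_disc(140.0)
        assert np.isnan(core_radius(state, "primary"))


class TestCompactness:
    def test_isolated_cell_is_zero(self, small_state):
        small_state.add_cell(10, 10, 0)
        assert compactness(small_state) == 0.0

    def test_large_packed_disc_tends_to_one(self):
        state, _ = gi.make_disc(400.0)
        assert compactness(state) > 0.9

    def test_matches_brute_force_average(self, rng):
        state = scattered_state(rng)
        n = state.geometry.n
        ids = state.live_ids()
        total = 0
        for k in ids:
            ci, cj = int(state.pos_i[k]), int(state.pos_j[k])
            cnt = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) == (0, 0):
                        continue
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < n and 0 <= nj < n and state.occ[ni, nj] != -1:
                        cnt += 1
            total += cnt
        assert compactness(state) == pytest.approx(total / (8.0 * ids.size))

    def test_detaching_a_boundary_cell_lowers_compactness(self):
        state, _ = gi.make_disc(140.0)
        before = compactness(state)
        ci, cj = state.geometry.centre_site
        # move the rim cell at (ci+7, cj) far away, N fixed
        rim = int(state.occ[ci + 7, cj])
        state.occ[ci + 7, cj] = -1
        state.pos_i[rim], state.pos_j[rim] = ci + 60, cj
        state.occ[ci + 60, cj] = rim
        assert compactness(state) < before


class TestSparseness:
    def test_packed_block_is_exactly_one(self, small_state):
        place(small_state, [(5 + a, 5 + b) for a in range(4) for b in range(4)])
        assert sparseness(small_state) == 1.0

    def test_two_distant_cells(self, small_state):
        place(small_state, [(2, 2), (2, 12)])
        assert sparseness(small_state) == 10.0

    def test_matches_all_pairs_oracle(self, rng):
        state = scattered_state(rng, n_cells=40)
        ids = state.live_ids()
        pts = np.column_stack([state.pos_i[ids], state.pos_j[ids]]).astype(float)
        nn = []
        for a in range(len(pts)):
            d = np.hypot(*(pts[a] - pts[np.arange(len(pts)) != a]).T)
            nn.append(d.min())
        assert sparseness(state) == pytest.approx(float(np.mean(nn)))

    def test_undefined_below_two_cells(self, small_state):
        small_state.add_cell(0, 0, 0)
        with pytest.raises(MetricUndefinedError):
            sparseness(small_state)

    def test_packed_disc_compact_and_sparseness_consistent(self):
        state, _ = gi.make_disc(300.0)
        assert compactness(state) > 0.85
        assert sparseness(state) == 1.0


class TestPhenotypeFrequencies:
    def test_single_phenotype(self, small_state):
        place(small_state, [(1, 1), (2, 2)], phenotype=7)
        freqs = phenotype_frequencies(small_state)
        assert freqs[7] == 1.0 and freqs.sum() == 1.0

    def test_balanced_mixture(self, small_state):
        for k, p in enumerate((0, 1, 6, 7)):
            place(small_state, [(k, 0), (k, 2)], phenotype=p)
        freqs = phenotype_frequencies(small_state)
        np.testing.assert_allclose(freqs[[0, 1, 6, 7]], 0.25)


class TestExpansionSpeed:
    def _frame(self, t, y):
        return pd.DataFrame({"time_h": t, "invasive_radius_um": y})

    def test_exact_linear_series(self):
        t = np.arange(0, 100, 8.0)
        assert expansion_speed(self._frame(t, 5.0 * t), (0, 96)) == pytest.approx(5.0)

    def test_constant_series_is_zero(self):
        t = np.arange(0, 100, 8.0)
        assert expansion_speed(self._frame(t, np.full_like(t, 140.0)), (0, 96)) == 0.0

    def test_window_restriction(self):
        t = np.arange(0, 100, 8.0)
        y = np.where(t < 24, 10.0 * t, 240.0 + 2.0 * (t - 24))
        assert expansion_speed(self._frame(t, y), (24, 96)) == pytest.approx(2.0)

    def test_noisy_linear_series_recovered(self, rng):
        t = np.arange(0, 200, 8.0)
        noise = rng.normal(0, 5.0, t.size)
        slope = expansion_speed(self._frame(t, 3.0 * t + noise), (0, 192))
        # OLS standard error bound for this noise level
        se = 5.0 / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(slope - 3.0) < 4 * se

    def test_too_few_points_rejected(self):
        with pytest.raises(MetricUndefinedError):
            expansion_speed(self._frame(np.array([0.0]), np.array([1.0])), (0, 10))


def test_largest_component_fraction_discriminates():
    rng = np.random.default_rng(0)
    cohesive, _ = gi.make_sprouted(140.0, 6, 200.0, rng)
    scattered, _ = gi.make_starburst(140.0, 30, 800.0, rng)
    assert largest_component_fraction(cohesive) == 1.0
    assert largest_component_fraction(scattered) < 1.0
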