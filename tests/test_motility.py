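"""Movement: kernel derivation, adhesion gating, walk statistics.

Oracles: direct algebra for the kernel quantities, exhaustive
enumeration of 3x3 contexts for admissibility, and the closed-form
second moment E[step^2] = 1.5 * p_move * h^2 for a free walker (the
factor 1.5 comes from the four diagonal Moore steps of length h*sqrt2).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import glioinvade as gi
from glioinvade.model_core import LatticeGeometry, TumourState
from glioinvade.motility import (
    MoveKernel,
    admissible_destinations,
    attempt_move,
    build_kernel,
    occupied_neighbours,
)

from conftest import place


class TestBuildKernel:
    def test_immotile(self):
        k = build_kernel(0.0, 20.0, 0.8)
        assert k.p_move == 0.0 and k.n_substeps == 1

    def test_substep_bound_is_h2_over_4d(self):
        # h^2/(4 D_c) = (20e-4 cm)^2 / (4 * 5e-9) = 200 s
        k = build_kernel(5e-9, 20.0, 10.0)  # t_r long enough not to bind
        assert k.k_s == pytest.approx(36000.0 / np.ceil(36000.0 / 200.0))
        assert k.p_move <= 1.0

    def test_reference_kernel_for_u87mg_motility(self):
        # D_c = 5e-9, h = 20 um, t_r = 0.8 h: 15 substeps of 192 s, p = 0.96
        k = build_kernel(5e-9, 20.0, 0.8)
        assert k.n_substeps == 15
        assert k.k_s == pytest.approx(192.0)
        assert k.p_move == pytest.approx(0.96)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_kernel(-1e-9, 20.0, 0.8)
        with pytest.raises(ValueError):
            build_kernel(1e-9, 20.0, -0.8)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        d_c=st.floats(min_value=1e-12, max_value=1e-6),
        h_um=st.floats(min_value=5.0, max_value=50.0),
        t_r_h=st.floats(min_value=0.1, max_value=2.0),
    )
    def test_kernel_invariants(self, d_c, h_um, t_r_h):
        """For any admissible parameters: p_move <= 1, substeps tile t_r
        exactly, and the total expected hop count 4*D_c*t_r/h^2 is
        conserved regardless of how t_r is substepped."""
        k = build_kernel(d_c, h_um, t_r_h)
        t_r_s = t_r_h * 3600.0
        h_cm = h_um * 1e-4
        assert 0.0 < k.p_move <= 1.0 + 1e-12
        assert k.n_substeps * k.k_s == pytest.approx(t_r_s, rel=1e-12)
        assert k.p_move == pytest.approx(4.0 * d_c * k.k_s / h_cm**2, rel=1e-12)
        assert k.n_substeps * k.p_move == pytest.approx(
            4.0 * d_c * t_r_s / h_cm**2, rel=1e-12
        )


class TestNeighbourCounting:
    def test_isolated_cell_scores_zero(self, small_state):
        place(small_state, [(10, 10)])
        assert occupied_neighbours(small_state, (10, 11), excluding=0) == 0

    def test_self_exclusion(self, small_state):
        # mover at centre of a full ring: the ring site it sits on is
        # excluded from its own destination counts
        ring = [(9 + di, 9 + dj) for di in range(3) for dj in range(3) if (di, dj) != (1, 1)]
        place(small_state, ring)
        mover = small_state.add_cell(10, 10, 0)
        assert occupied_neighbours(small_state, (10, 10), excluding=None) == 8
        assert occupied_neighbours(small_state, (10, 10), excluding=mover) == 8
        # a site adjacent to the mover, counting everyone vs excluding it
        assert occupied_neighbours(small_state, (11, 11)) - occupied_neighbours(
            small_state, (11, 11), excluding=mover
        ) == 1

    def test_out_of_bounds_site_rejected(self, small_state):
        with pytest.raises(IndexError):
            occupied_neighbours(small_state, (-1, 0))

    def test_border_neighbourhood_truncated(self, small_state):
        place(small_state, [(0, 1)])
        assert occupied_neighbours(small_state, (0, 0)) == 1


class TestAdmissibility:
    def test_schematic_low_adhesion_moves_left(self, small_state):
        """A preference-0 cell with cells packed on its right may move
        only to the three empty left positions (each scoring 0)."""
        mover = small_state.add_cell(10, 10, 0)
        place(small_state, [(9, 11), (10, 11), (11, 11)])  # column to the right
        dests = admissible_destinations(small_state, mover)
        assert dests == {(9, 9), (10, 9), (11, 9)}

    def test_fully_enclosed_cell_has_no_destination(self, small_state):
        ring = [(9 + di, 9 + dj) for di in range(3) for dj in range(3) if (di, dj) != (1, 1)]
        place(small_state, ring)
        mover = small_state.add_cell(10, 10, 0)
        assert admissible_destinations(small_state, mover) == set()

    @pytest.mark.parametrize("pref,expected_n", [(0, 8), (1, 0), (7, 0)])
    def test_isolated_cell_admissible_counts(self, small_state, pref, expected_n):
        # in empty space every adjacent site scores 0: preference 0 sees
        # all 8, any other preference sees none
        mover = small_state.add_cell(10, 10, pref)
        assert len(admissible_destinations(small_state, mover)) == expected_n

    def test_against_exhaustive_enumeration(self, rng):
        """Random crowded configurations vs a brute-force oracle."""
        for trial in range(20):
            state = TumourState(LatticeGeometry(side_mm=0.2, site_um=20.0))  # 10x10
            sites = [(i, j) for i in range(10) for j in range(10)]
            chosen = rng.choice(100, size=30, replace=False)
            for k in chosen:
                state.add_cell(*sites[k], int(rng.integers(0, 8)))
            cid = int(rng.choice(state.live_ids()))
            ci, cj = int(state.pos_i[cid]), int(state.pos_j[cid])
            pref = int(state.phenotype[cid])
            expected = set()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) == (0, 0):
                        continue
                    ni, nj = ci + di, cj + dj
                    if not (0 <= ni < 10 and 0 <= nj < 10) or state.occ[ni, nj] != -1:
                        continue
                    cnt = 0
                    for ei in (-1, 0, 1):
                        for ej in (-1, 0, 1):
                            if (ei, ej) == (0, 0):
                                continue
                            mi, mj = ni + ei, nj + ej
                            if 0 <= mi < 10 and 0 <= mj < 10:
                                v = state.occ[mi, mj]
                                if v >= 0 and v != cid:
                                    cnt += 1
                    if cnt == pref:
                        expected.add((ni, nj))
            assert admissible_destinations(state, cid) == expected


class TestAttemptMove:
    def test_zero_probability_never_moves(self, small_state, rng):
        mover = small_state.add_cell(10, 10, 0)
        attempt_move(small_state, mover, MoveKernel(0.0, 2880.0, 1, 0.0), rng)
        assert (small_state.pos_i[mover], small_state.pos_j[mover]) == (10, 10)

    def test_single_hop_is_uniform_over_moore_sites(self, rng):
        """10^5 single-substep hops of a lone preference-0 cell land
        uniformly on the 8 neighbours (chi-square)."""
        kernel = MoveKernel(1e-9, 1.0, 1, 1.0)
        counts = {}
        state = TumourState(LatticeGeometry(side_mm=0.1, site_um=20.0))  # 5x5
        n_draws = 10**5
        for _ in range(n_draws):
            mover = state.add_cell(2, 2, 0)
            attempt_move(state, mover, kernel, rng)
            dest = (int(state.pos_i[mover]) - 2, int(state.pos_j[mover]) - 2)
            counts[dest] = counts.get(dest, 0) + 1
            state.kill_cell(mover, log=False)
        assert (0, 0) not in counts  # p_move = 1 with 8 admissible: always hops
        observed = np.array([counts.get(o, 0) for o in
                             [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                              if (di, dj) != (0, 0)]])
        p = stats.chisquare(observed).pvalue
        assert p > 1e-4

    def test_free_walker_msd_matches_closed_form(self, rng):
        """Ensemble MSD of free preference-0 walkers equals
        n_substeps * 1.5 * p_move * h^2 within 3 sigma (10^3 walkers)."""
        h_um = 20.0
        kernel = build_kernel(5e-9, h_um, 0.8)
        n_intervals = 10  # 8 h of walking
        n_walkers = 1000
        state = TumourState(LatticeGeometry(side_mm=4.0, site_um=h_um))  # 200x200
        r2 = np.empty(n_walkers)
        for w in range(n_walkers):
            mover = state.add_cell(100, 100, 0)
            for _ in range(n_intervals):
                attempt_move(state, mover, kernel, rng)
            di = float(state.pos_i[mover]) - 100.0
            dj = float(state.pos_j[mover]) - 100.0
            r2[w] = (di**2 + dj**2) * h_um**2
            state.kill_cell(mover, log=False)
        expected = n_intervals * kernel.n_substeps * 1.5 * kernel.p_move * h_um**2
        sem = r2.std(ddof=1) / np.sqrt(n_walkers)
        assert abs(r2.mean() - expected) < 3.0 * sem

    def test_move_preserves_exclusion_and_registry(self, rng):
        state = TumourState(LatticeGeometry(side_mm=0.3, site_um=20.0))  # 15x15
        for i in range(15):
            for j in range(15):
                if rng.random() < 0.5:
                    state.add_cell(i, j, int(rng.integers(0, 8)))
        kernel = build_kernel(2e-8, 20.0, 0.8)
        for cid in state.live_ids():
            attempt_move(state, int(cid), kernel, rng)
        assert gi.audit_consistency(state)

    def test_packed_preference7_disc_is_frozen(self, rng):
        """In an all-preference-7 packed disc no admissible destination
        exists anywhere (interior has no empty neighbour; rim sites
        score far below 7), so every position is invariant."""
        state, _ = gi.make_disc(140.0, phenotype=7)
        ids = state.live_ids()
        pos_before = [(int(state.pos_i[c]), int(state.pos_j[c])) for c in ids]
        kernel = build_kernel(2e-8, 20.0, 0.8)
        for cid in ids:
            attempt_move(state, int(cid), kernel, rng)
        pos_after = [(int(state.pos_i[c]), int(state.pos_j[c])) for c in ids]
        assert pos_before == pos_after
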