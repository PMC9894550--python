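"""Folding kinetics: elementary moves, transition paths, MFPT, KMC."""

import math
import random

import numpy as np
import pytest

from conftest import random_sequence, random_structure
from ribodyn.energy import EnergyParams
from ribodyn.kinetics import (RateModel, TransitionPath, aggregated_path_rates,
                              apply_move, elementary_moves, exact_mfpt,
                              find_path_bfs, find_path_mfp, greedy_path,
                              kmc_simulate, path_mfpt)

MODEL = RateModel()
SMALL_HAIRPIN = ("GGCAAAAGCC", "(((....)))")


def fully_open(db: str) -> bool:
    return "(" not in db


class TestRateModel:
    @pytest.mark.parametrize("rule", ["kawasaki", "metropolis"])
    def test_detailed_balance_to_machine_precision(self, rule, params):
        model = RateModel(k0=1e6, rule=rule)
        rng = random.Random(3)
        for _ in range(200):
            ddG = rng.uniform(-8, 8)
            ratio = model.rate(ddG, params.beta) / model.rate(-ddG, params.beta)
            assert ratio == pytest.approx(math.exp(-params.beta * ddG), rel=1e-12)

    def test_unknown_rule_rejected(self, params):
        with pytest.raises(ValueError):
            RateModel(rule="glauber").rate(1.0, params.beta)


class TestElementaryMoves:
    def test_moves_are_involutive_and_valid(self, params):
        rng = random.Random(9)
        for _ in range(20):
            seq = random_sequence(rng, 25)
            db = random_structure(seq, rng)
            for mv in elementary_moves(seq, db):
                nxt = apply_move(db, mv)
                back = (-mv[0], -mv[1])
                assert apply_move(nxt, back) == db

    def test_mask_excludes_positions(self):
        seq, db = "GGGAAAACCC", ".........."
        moves = elementary_moves(seq, db, mask=frozenset([1, 2, 3]))
        assert all(m[0] not in (1, 2, 3) for m in moves if m[0] > 0)


class TestPathMfpt:
    def test_two_state_path(self):
        p = TransitionPath(["..", ".."], [0.0, 0.0], k_fwd=[5.0], k_bwd=[1.0])
        assert path_mfpt(p) == pytest.approx(0.2)

    def test_three_state_symmetric_chain(self):
        k = 7.0
        p = TransitionPath(["a", "b", "c"], [0.0] * 3,
                           k_fwd=[k, k], k_bwd=[k, k])
        assert path_mfpt(p) == pytest.approx(3.0 / k)

    def test_matches_fundamental_matrix_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = rng.integers(2, 12)
            kf = rng.uniform(0.1, 50.0, n - 1)
            kb = rng.uniform(0.1, 50.0, n - 1)
            p = TransitionPath([str(i) for i in range(n)], [0.0] * n,
                               k_fwd=list(kf), k_bwd=list(kb))
            # fundamental matrix on transient states 0..n-2 (state 0 reflecting)
            Q = np.zeros((n - 1, n - 1))
            for i in range(n - 1):
                out = kf[i] + (kb[i - 1] if i > 0 else 0.0)
                Q[i, i] = -out
                if i > 0:
                    Q[i, i - 1] = kb[i - 1]
                if i < n - 2:
                    Q[i, i + 1] = kf[i]
            tau = np.linalg.solve(Q, -np.ones(n - 1))
            assert path_mfpt(p) == pytest.approx(tau[0], rel=1e-10)

    def test_zero_rate_rejected(self):
        p = TransitionPath(["a", "b"], [0.0, 0.0], k_fwd=[0.0], k_bwd=[0.0])
        with pytest.raises(ValueError):
            path_mfpt(p)


class TestPathFinding:
    def test_identical_structures_give_single_state_path(self, params):
        seq, db = SMALL_HAIRPIN
        for fn in (greedy_path, find_path_bfs, find_path_mfp):
            p = fn(seq, db, db, params, MODEL)
            assert len(p.states) == 1 and p.barrier == 0.0

    def test_one_pair_difference(self, params):
        seq = "GGCAAAAGCC"
        s1, s2 = "(((....)))", ".((....))."
        p = greedy_path(seq, s1, s2, params, MODEL)
        assert 2 <= len(p.states) <= 3

    def test_adjacent_states_differ_by_one_pair(self, params):
        rng = random.Random(21)
        for _ in range(10):
            seq = random_sequence(rng, 16)
            s1 = random_structure(seq, rng, 10)
            s2 = random_structure(seq, rng, 10)
            p = find_path_bfs(seq, s1, s2, params, MODEL, width=5, slack=2)
            for a, b in zip(p.states, p.states[1:]):
                diff = sum(x != y for x, y in zip(a, b))
                assert diff == 2

    def test_bfs_barrier_never_exceeds_greedy(self, params):
        rng = random.Random(33)
        for _ in range(25):
            seq = random_sequence(rng, 16)
            s1 = random_structure(seq, rng, 10)
            s2 = random_structure(seq, rng, 10)
            g = greedy_path(seq, s1, s2, params, MODEL)
            b = find_path_bfs(seq, s1, s2, params, MODEL, width=10, slack=4)
            assert b.barrier <= g.barrier + 1e-9

    def test_mfp_selection_never_exceeds_greedy_mfpt(self, params):
        rng = random.Random(44)
        for _ in range(10):
            seq = random_sequence(rng, 16)
            s1 = random_structure(seq, rng, 10)
            s2 = random_structure(seq, rng, 10)
            g = greedy_path(seq, s1, s2, params, MODEL)
            m = find_path_mfp(seq, s1, s2, params, MODEL, width=10,
                              aggregate=False)
            assert m.mfpt() <= g.mfpt() * (1 + 1e-9)

    def test_mfp_two_state_equals_inverse_rate(self, params):
        # single addable pair: one-move path, MFPT = 1/k+
        seq, open_db, closed = "GAAAU", ".....", "(...)"
        p = find_path_mfp(seq, open_db, closed, params, MODEL)
        assert len(p.states) == 2
        assert p.mfpt() == pytest.approx(1.0 / p.k_fwd[0])


class TestKMC:
    def test_two_state_toy_matches_analytic_mean(self, params):
        # GAAAU supports exactly one pair; unfolding is a one-step process
        seq, closed = "GAAAU", "(...)"
        p = find_path_mfp(seq, closed, ".....", params, MODEL)
        analytic = 1.0 / p.k_fwd[0]
        res = kmc_simulate(seq, closed, fully_open, params, MODEL,
                           n_traj=10_000, seed=4)
        assert res.mean == pytest.approx(analytic, abs=3 * res.se)

    def test_matches_exact_first_step_analysis(self, params):
        seq, db = SMALL_HAIRPIN
        exact = exact_mfpt(seq, db, fully_open, params, MODEL, energy_cap=10.0)
        res = kmc_simulate(seq, db, fully_open, params, MODEL,
                           n_traj=400, seed=8)
        assert res.mean == pytest.approx(exact, abs=3 * res.se)

    def test_reproducible_per_seed(self, params):
        seq, db = SMALL_HAIRPIN
        a = kmc_simulate(seq, db, fully_open, params, MODEL, n_traj=50, seed=1)
        b = kmc_simulate(seq, db, fully_open, params, MODEL, n_traj=50, seed=1)
        assert np.array_equal(a.times, b.times)

    def test_unreachable_absorbing_state_reported(self, params):
        with pytest.raises(RuntimeError, match="step cap|unreachable"):
            kmc_simulate("GGCAAAAGCC", "..........",
                         lambda db: db.count("(") > 4,  # impossible
                         params, MODEL, n_traj=2, seed=0, step_cap=2000)


class TestExactMfpt:
    def test_cap_insensitive_once_converged(self, params):
        seq, db = SMALL_HAIRPIN
        lo = exact_mfpt(seq, db, fully_open, params, MODEL, energy_cap=8.0)
        hi = exact_mfpt(seq, db, fully_open, params, MODEL, energy_cap=11.0)
        assert lo == pytest.approx(hi, rel=0.02)

    def test_aggregated_path_tracks_exact_chain(self, params):
        seq, db = SMALL_HAIRPIN
        exact = exact_mfpt(seq, db, fully_open, params, MODEL, energy_cap=10.0)
        path = find_path_mfp(seq, db, "." * len(seq), params, MODEL)
        assert 0.5 * exact <= path.mfpt() <= 2.0 * exact
        single = find_path_mfp(seq, db, "." * len(seq), params, MODEL,
                               aggregate=False)
        assert path.mfpt() <= single.mfpt()
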