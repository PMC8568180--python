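"""Lattice model: local rules, sweeps, perturbations, physics sanity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isingcsd import (
    LatticeConfig,
    energy_diff,
    flip_decision,
    magnetization,
    metropolis_sweep,
    neighbor_sum,
    perturb_alignment,
    random_lattice,
    simulate_lattice,
    site_state_probability,
)


def checkerboard(L):
    g = np.indices((L, L)).sum(axis=0) % 2
    return np.where(g == 0, 1, -1).astype(np.int8)


class TestLocalRules:
    def test_neighbor_sum_uniform_and_checkerboard(self, rng):
        ones = np.ones((6, 6), dtype=np.int8)
        assert neighbor_sum(ones, 0, 0) == 4
        assert neighbor_sum(-ones, 3, 5) == -4
        cb = checkerboard(6)
        for i, j in [(0, 0), (2, 3), (5, 5)]:
            assert neighbor_sum(cb, i, j) == -4 * cb[i, j]

    def test_neighbor_sum_periodic_wrap(self):
        g = -np.ones((4, 4), dtype=np.int8)
        g[0, 1] = 1  # wraps around to be a neighbor of (3, 1)
        assert neighbor_sum(g, 3, 1) == -2

    def test_neighbor_sum_out_of_range(self):
        with pytest.raises(IndexError):
            neighbor_sum(np.ones((4, 4), dtype=np.int8), 4, 0)

    @pytest.mark.parametrize(
        "S, NB, H, expected",
        [(1, 4, 0.0, 8.0), (-1, 2, 0.2, -3.6), (1, 0, 0.0, 0.0)],
    )
    def test_energy_diff(self, S, NB, H, expected):
        assert energy_diff(S, NB, H) == pytest.approx(expected)

    def test_flip_decision_branches(self):
        assert flip_decision(-1.0, 0.5, 0.999)  # downhill always accepted
        assert flip_decision(0.0, 0.5, 0.999)  # boundary included
        thresh = math.exp(-4.0)
        assert flip_decision(8.0, 2.0, thresh * 0.99)
        assert not flip_decision(8.0, 2.0, thresh * 1.01)
        with pytest.raises(ValueError):
            flip_decision(1.0, 0.0, 0.5)


class TestSweep:
    def test_frozen_at_zero_temperature(self, rng):
        spins = np.ones((10, 10), dtype=np.int8)
        metropolis_sweep(spins, 1e-6, 0.0, rng)
        assert np.all(spins == 1)

    def test_defect_heals_at_zero_temperature(self, rng):
        # every visit to the defect flips it (Ediff = -8); sweeps of L^2
        # attempts visit it with prob 1-(1-1/L^2)^(L^2) ~ 0.63 per sweep
        spins = np.ones((8, 8), dtype=np.int8)
        spins[3, 3] = -1
        for _ in range(20):
            metropolis_sweep(spins, 1e-6, 0.0, rng)
        assert np.all(spins == 1)

    def test_spin_domain_closed_and_magnetization_bounded(self, rng):
        spins = random_lattice(12, rng)
        for _ in range(5):
            metropolis_sweep(spins, 2.5, 0.1, rng)
        assert set(np.unique(spins)) <= {-1, 1}
        assert -1.0 <= magnetization(spins) <= 1.0

    def test_strong_field_aligns_from_any_start(self, rng):
        # Ediff = 2S(NB - H): for |H| > 4 every misaligned spin flips at T->0;
        # positive H favours spin -1 under this sign convention
        spins = random_lattice(16, rng)
        for _ in range(5):
            metropolis_sweep(spins, 1e-6, 5.0, rng)
        assert np.all(spins == -1)

    def test_magnetization_values(self):
        assert magnetization(np.ones((4, 4), dtype=np.int8)) == 1.0
        assert magnetization(-np.ones((4, 4), dtype=np.int8)) == -1.0
        assert magnetization(checkerboard(4)) == 0.0


class TestSimulate:
    def test_ordered_phase_retains_magnetization(self):
        high = []
        for seed in range(10):
            cfg = LatticeConfig(L=20, temperature=1.5, field_schedule=0.0,
                                sweeps=100, seed=seed, init="up")
            high.append(simulate_lattice(cfg).values[-1])
        assert np.mean(np.asarray(high) > 0.9) >= 0.95

    def test_disordered_phase_near_zero(self):
        vals = []
        for seed in range(5):
            cfg = LatticeConfig(L=20, temperature=10.0, field_schedule=0.0,
                                sweeps=200, seed=seed, init="random")
            vals.append(simulate_lattice(cfg).values[50:].mean())
        assert abs(np.mean(vals)) < 0.05

    def test_seed_determinism(self):
        cfg = LatticeConfig(L=16, temperature=2.12, field_schedule=0.05,
                            sweeps=30, seed=7, init="random")
        a = simulate_lattice(cfg).values
        b = simulate_lattice(cfg).values
        assert np.array_equal(a, b)

    def test_order_disorder_crossover(self):
        """|mean magnetization| at T=1.5 exceeds T=3.5 at 3 sigma (H=0)."""
        lows, highs = [], []
        for seed in range(20):
            for T, out in [(1.5, lows), (3.5, highs)]:
                cfg = LatticeConfig(L=50, temperature=T, field_schedule=0.0,
                                    sweeps=500, record_every=5, seed=seed,
                                    init="up")
                out.append(abs(simulate_lattice(cfg).values[50:].mean()))
        lows, highs = np.asarray(lows), np.asarray(highs)
        gap = lows.mean() - highs.mean()
        se = math.sqrt(lows.var() / len(lows) + highs.var() / len(highs))
        assert gap > 3 * se

    def test_record_every_thins_output(self):
        cfg = LatticeConfig(L=8, temperature=2.0, sweeps=40, record_every=10,
                            seed=0)
        assert len(simulate_lattice(cfg)) == 5  # initial + 4 records


class TestPerturbAlignment:
    def test_extremes(self, rng):
        spins = -np.ones((10, 10), dtype=np.int8)
        flipped = perturb_alignment(spins, 0.0, rng, equilibrium_sign=-1)
        assert magnetization(flipped) == 1.0
        kept = perturb_alignment(spins, 1.0, rng, equilibrium_sign=-1)
        assert magnetization(kept) == -1.0

    def test_half_probability_unordered(self):
        # binomial standard error: |M| < 3/L for L=100 in ~99% of draws
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spins = -np.ones((100, 100), dtype=np.int8)
            out = perturb_alignment(spins, 0.5, rng, equilibrium_sign=-1)
            hits += abs(magnetization(out)) < 3 / 100
        assert hits >= 18

    @given(r=st.floats(0.0, 1.0))
    def test_magnetization_matches_alignment_probability(self, r):
        rng = np.random.default_rng(0)
        spins = np.ones((50, 50), dtype=np.int8)
        out = perturb_alignment(spins, r, rng, equilibrium_sign=1)
        assert abs(magnetization(out) - (2 * r - 1)) < 0.1

    def test_invalid_inputs(self, rng):
        spins = np.ones((4, 4), dtype=np.int8)
        with pytest.raises(ValueError):
            perturb_alignment(spins, 1.5, rng, equilibrium_sign=1)
        with pytest.raises(ValueError):
            perturb_alignment(spins, 0.5, rng, equilibrium_sign=0)


class TestSiteProbability:
    def test_frozen_ensemble(self):
        traces = -np.ones((5, 20), dtype=np.int8)
        trace = site_state_probability(traces, -1)
        assert np.all(trace.probability == 1.0)

    def test_complementary_states(self, rng):
        traces = rng.choice([-1, 1], size=(8, 30)).astype(np.int8)
        p_minus = site_state_probability(traces, -1).probability
        p_plus = site_state_probability(traces, 1).probability
        assert np.allclose(p_minus + p_plus, 1.0)

    def test_ordered_phase_low_minus_probability(self):
        traces = []
        for seed in range(6):
            cfg = LatticeConfig(L=16, temperature=1.2, field_schedule=0.0,
                                sweeps=40, seed=seed, init="up")
            traj = simulate_lattice(cfg, track_site=(8, 8))
            traces.append(traj.meta["site_trace"])
        trace = site_state_probability(np.asarray(traces), -1, site=(8, 8))
        assert np.all(trace.probability < 0.05)

    def test_needs_ensemble(self):
        with pytest.raises(ValueError):
            site_state_probability(np.ones((1, 10)), -1)
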