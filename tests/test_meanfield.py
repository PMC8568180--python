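"""Mean-field model: dynamics, equilibria, folds, equilibrium curves."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isingcsd import (
    MeanFieldConfig,
    NoBistableRegionError,
    equilibrium_curves,
    fold_points,
    meanfield_equilibria,
    simulate_meanfield,
    step_meanfield,
)


def fixed_point_iterate(coupling, field, start, n=500):
    """Independent oracle: iterate M <- tanh(c*M + H) to a stable root."""
    m = start
    for _ in range(n):
        m = math.tanh(coupling * m + field)
    return m


class TestStep:
    @pytest.mark.parametrize(
        "m, T, H, expected",
        [
            (0.0, 2.12, 0.0, 0.0),  # tanh(0)=0: origin is a fixed point
            (1.0, 1e-12, 0.0, 0.9),  # pure decay, increment -1 * dt
            (0.5, 2.0, 0.0, 0.5 + (-0.5 + math.tanh(1.0)) * 0.1),
        ],
    )
    def test_deterministic_update(self, m, T, H, expected):
        cfg = MeanFieldConfig(temperature=T, external_field=H, dt=0.1, sigma=0.0)
        assert step_meanfield(m, cfg, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MeanFieldConfig(dt=0.0)
        with pytest.raises(ValueError):
            MeanFieldConfig(sigma=-0.1)
        with pytest.raises(ValueError):
            MeanFieldConfig(n_steps=0)
        with pytest.raises(ValueError):
            MeanFieldConfig(m0=2.0)


class TestSimulate:
    def test_subcritical_decay_to_zero(self):
        cfg = MeanFieldConfig(temperature=0.5, external_field=0.0, sigma=0.0,
                              m0=0.8, n_steps=200)
        traj = simulate_meanfield(cfg)
        assert len(traj) == 201
        assert np.all(np.diff(np.abs(traj.values)) <= 1e-15)
        assert abs(traj.values[-1]) < 1e-3

    def test_fixed_point_stays_constant(self):
        root = fixed_point_iterate(2.0, 0.0, 0.5)
        cfg = MeanFieldConfig(temperature=2.0, sigma=0.0, m0=root, n_steps=100)
        traj = simulate_meanfield(cfg)
        assert np.allclose(traj.values, root, atol=1e-12)

    def test_seed_determinism(self):
        cfg = MeanFieldConfig(temperature=2.12, external_field=-0.7, sigma=0.01,
                              m0=-1.0, n_steps=500, seed=42)
        a = simulate_meanfield(cfg).values
        b = simulate_meanfield(cfg).values
        assert np.array_equal(a, b)

    def test_noise_free_convergence_to_stable_root(self):
        root = fixed_point_iterate(2.0, 0.1, 1.0)
        cfg = MeanFieldConfig(temperature=2.0, external_field=0.1, sigma=0.0,
                              m0=0.5, n_steps=5000)
        traj = simulate_meanfield(cfg)
        assert abs(traj.values[-1] - root) < 1e-6

    @given(
        H=st.floats(-0.5, 0.5),
        m0=st.floats(-1.2, 1.2),
        T=st.floats(0.2, 3.0),
    )
    def test_odd_symmetry(self, H, m0, T):
        """Simulating (H, m0) and (-H, -m0) gives exact mirror trajectories."""
        a = simulate_meanfield(MeanFieldConfig(
            temperature=T, external_field=H, sigma=0.0, m0=m0, n_steps=50))
        b = simulate_meanfield(MeanFieldConfig(
            temperature=T, external_field=-H, sigma=0.0, m0=-m0, n_steps=50))
        assert np.allclose(a.values, -b.values, atol=1e-14)

    def test_field_ramp_schedule(self):
        ramp = np.linspace(-0.5, 0.5, 300)
        cfg = MeanFieldConfig(temperature=2.12, external_field=ramp, sigma=0.0,
                              m0=-1.0, n_steps=300)
        traj = simulate_meanfield(cfg)
        assert len(traj) == 301
        assert len(traj.parameter_array()) == 301


class TestEquilibria:
    def test_subcritical_single_stable_root(self):
        eq = meanfield_equilibria(0.5, 0.0)
        assert eq == [(pytest.approx(0.0, abs=1e-9), "stable")]

    def test_supercritical_roots_match_iteration_oracle(self):
        eq = meanfield_equilibria(2.0, 0.0)
        assert len(eq) == 3
        roots = [r for r, _ in eq]
        stabilities = [s for _, s in eq]
        oracle = fixed_point_iterate(2.0, 0.0, 0.5)
        assert roots[2] == pytest.approx(oracle, abs=1e-4)
        assert roots[0] == pytest.approx(-oracle, abs=1e-4)
        assert stabilities == ["stable", "unstable", "stable"]

    def test_residuals_below_1e9(self):
        for T, H in [(2.0, 0.0), (2.12, -0.3), (0.8, 0.2), (1.5, 0.05)]:
            for root, _ in meanfield_equilibria(T, H):
                assert abs(root - math.tanh(T * root + H)) < 1e-9

    def test_symmetric_root_pairs_at_zero_field(self):
        eq = meanfield_equilibria(2.0, 0.0)
        roots = sorted(r for r, _ in eq)
        assert roots[1] == pytest.approx(0.0, abs=1e-12)
        assert roots[0] == pytest.approx(-roots[2], abs=1e-9)


class TestFoldPoints:
    def test_closed_form_matches_root_counting(self):
        """Brute-force oracle: count roots of the self-consistency equation
        on a fine field grid; the 3-root window's edge is the fold."""
        T = 2.12
        M = np.linspace(-1, 1, 4001)
        three_root_fields = []
        for H in np.arange(0.55, 0.68, 1e-3):
            f = M - np.tanh(T * M + H)
            n_roots = int(np.sum(np.sign(f[:-1]) != np.sign(f[1:])))
            if n_roots == 3:
                three_root_fields.append(H)
        brute = max(three_root_fields)
        lo, hi = fold_points(T)
        assert hi == pytest.approx(brute, abs=2e-3)
        assert lo == -hi

    def test_pitchfork_limit(self):
        lo, hi = fold_points(1.0 + 1e-9)
        assert abs(hi) < 1e-4 and abs(lo) < 1e-4

    def test_no_bistability_below_threshold(self):
        with pytest.raises(NoBistableRegionError):
            fold_points(0.9)


class TestEquilibriumCurves:
    def test_subcritical_single_branch_through_origin(self):
        grid = np.linspace(-0.3, 0.3, 61)
        branches = equilibrium_curves(0.5, grid)
        assert len(branches) == 1
        br = branches[0]
        assert np.all(br.stability == "stable")
        mid = np.argmin(np.abs(br.parameter))
        assert br.state[mid] == pytest.approx(0.0, abs=1e-9)

    def test_bistable_column_count_and_continuity(self):
        grid = np.linspace(-0.3, 0.3, 121)
        branches = equilibrium_curves(2.0, grid)
        at_zero = [
            br.state[np.isclose(br.parameter, 0.0)]
            for br in branches
        ]
        assert sum(len(a) for a in at_zero) == 3
        for br in branches:
            assert np.all(np.abs(np.diff(br.state)) < 0.1)

    def test_stability_flips_only_at_folds(self):
        # inside the bistable window every branch keeps one stability label
        w = fold_points(2.0)[1]
        grid = np.linspace(-0.9 * w, 0.9 * w, 41)
        for br in equilibrium_curves(2.0, grid):
            assert len(set(br.stability)) == 1
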