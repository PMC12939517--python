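"""Unit and property tests of the lattice cluster-gating model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coopgate as cg
from coopgate.gating import initial_state, simulate_reference


def make_state(rc, b=14):
    return cg.ClusterState(np.asarray(rc, dtype=np.int64), -b, b)


class TestJumpProbabilities:
    @pytest.mark.parametrize("du, q, p", [
        (0.0, 0.5, 0.5),
        (1.0, 0.75, 0.25),
        (2.0, 1.0, 0.0),
        (-2.0, 0.0, 1.0),
    ])
    def test_tabulated_cases(self, du, q, p):
        ql, pr = cg.jump_probabilities(du)
        assert ql == pytest.approx(q, abs=1e-12)
        assert pr == pytest.approx(p, abs=1e-12)

    def test_out_of_range_energy_rejected(self):
        with pytest.raises(cg.InvalidParameterError):
            cg.jump_probabilities(3.0)

    @given(st.floats(-2.0, 2.0), st.floats(0.5, 3.0))
    def test_probability_conservation(self, du, kT):
        ql, pr = cg.jump_probabilities(du * kT, kT=kT)
        assert ql + pr == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= ql <= 1.0 and 0.0 <= pr <= 1.0


class TestLocalGradient:
    def test_flat_at_half_activation(self):
        params = cg.ModelParams(n_channels=1)
        state = make_state([5])
        for x in (-10, -5, -2, 2, 5, 10):
            assert cg.local_gradient(x, state, 0, params) == pytest.approx(0.0)

    def test_barrier_slopes_next_to_threshold(self):
        params = cg.ModelParams(n_channels=1, u_tp=2.0)
        state = make_state([1])
        assert cg.local_gradient(-1, state, 0, params) == pytest.approx(2.0 / 1.5)
        assert cg.local_gradient(+1, state, 0, params) == pytest.approx(-2.0 / 1.5)

    def test_barrier_is_drift_independent(self):
        params = cg.ModelParams(n_channels=1, drift=0.5)
        state = make_state([1])
        assert cg.local_gradient(1, state, 0, params) == pytest.approx(-2.0 / 1.5)

    def test_ramp_combines_drift_and_cooperation(self):
        # activation force lowers the slope, open neighbors add their term
        params = cg.ModelParams(n_channels=4, drift=0.1, coop_drift=0.1)
        state = make_state([5, 5, 5, 5])
        expected = -0.1 + 3 * 0.1
        assert cg.local_gradient(-8, state, 3, params) == pytest.approx(expected)
        assert cg.local_gradient(8, state, 3, params) == pytest.approx(expected)

    def test_matches_explicit_potential_difference(self):
        params = cg.ModelParams(n_channels=2, drift=0.3, coop_drift=-0.05)
        state = make_state([3, -4])
        for x in (-12, -3, -1, 1, 2, 9):
            direct = (cg.potential_energy(x + 0.5, state, 1, params)
                      - cg.potential_energy(x - 0.5, state, 1, params))
            assert cg.local_gradient(x, state, 1, params) == pytest.approx(direct)

    def test_positions_outside_interval_rejected(self):
        params = cg.ModelParams(n_channels=1)
        state = make_state([5])
        for x in (0, -14, 14, 20):
            with pytest.raises(cg.InvalidParameterError):
                cg.local_gradient(x, state, 0, params)

    def test_potential_peak_height(self):
        params = cg.ModelParams(n_channels=1, u_tp=2.0)
        state = make_state([5])
        peak = cg.potential_energy(0.0, state, 0, params)
        ramp_end = cg.potential_energy(-1.5, state, 0, params)
        assert peak - ramp_end == pytest.approx(2.0)
        # symmetric barrier: same offset reached on the right
        assert cg.potential_energy(1.5, state, 0, params) == pytest.approx(ramp_end)


class TestStepChannels:
    def test_threshold_skip(self, scripted_rng):
        params = cg.ModelParams(n_channels=1)
        state = make_state([-1])
        new = cg.step_channels(state, params, scripted_rng([0.99]))  # forced right
        assert new.rc_positions[0] == 1

    def test_threshold_skip_mirror(self, scripted_rng):
        params = cg.ModelParams(n_channels=1)
        state = make_state([1])
        new = cg.step_channels(state, params, scripted_rng([0.0]))  # forced left
        assert new.rc_positions[0] == -1

    def test_boundary_rejection(self, scripted_rng):
        params = cg.ModelParams(n_channels=1)
        state = make_state([13])  # b2 - 1
        new = cg.step_channels(state, params, scripted_rng([0.99]))
        assert new.rc_positions[0] == 13

    def test_moves_use_pattern_at_step_entry(self, scripted_rng):
        # channel 0 crosses to open, but channel 1 must see the entry pattern
        # (0 open neighbors -> flat ramp -> q = 1/2 exactly)
        params = cg.ModelParams(n_channels=2, coop_drift=-0.1)
        state = make_state([-1, -5])
        new = cg.step_channels(state, params, scripted_rng([0.99, 0.49]))
        assert new.rc_positions[0] == 1
        assert new.rc_positions[1] == -6   # draw 0.49 < q=0.5: left on flat ramp

    def test_flat_potential_move_frequency(self):
        # empirical right-move frequency at a ramp site is 1/2 within 3 sigma
        params = cg.ModelParams(n_channels=1)
        rng = np.random.default_rng(2024)
        n, right = 20_000, 0
        for _ in range(n):
            state = make_state([5])
            new = cg.step_channels(state, params, rng)
            right += int(new.rc_positions[0] == 6)
        freq = right / n
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestStepBoundaries:
    def test_outward_reflection_at_double_bmax(self, scripted_rng):
        params = cg.ModelParams(n_channels=1, b_max=14)
        state = cg.ClusterState(np.array([5]), -(2 * 14 - 1), 2 * 14 - 1)
        new = cg.step_boundaries(state, params, scripted_rng([0.9]))
        assert (new.b1, new.b2) == (state.b1, state.b2)

    def test_inward_reflection_at_threshold(self, scripted_rng):
        params = cg.ModelParams(n_channels=1)
        state = cg.ClusterState(np.array([1]), -2, 2)
        new = cg.step_boundaries(state, params, scripted_rng([0.1]))
        assert (new.b1, new.b2) == (-2, 2)

    def test_inward_move_pushes_overtaken_rc(self, scripted_rng):
        params = cg.ModelParams(n_channels=2)
        state = cg.ClusterState(np.array([13, -13]), -14, 14)
        new = cg.step_boundaries(state, params, scripted_rng([0.1]))
        assert (new.b1, new.b2) == (-13, 13)
        assert list(new.rc_positions) == [12, -12]  # open/closed states kept

    def test_mirror_symmetry_is_preserved(self):
        params = cg.ModelParams(n_channels=1)
        state = cg.ClusterState(np.array([3]), -14, 14)
        rng = np.random.default_rng(5)
        for _ in range(500):
            state = cg.step_boundaries(state, params, rng)
            assert state.b2 - state.tp == state.tp - state.b1
            assert 2 <= state.b2 < 2 * params.b_max


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [
        {"n_channels": 0},
        {"b_max": 1},
        {"timescale_ratio": 0},
        {"n_dwells": 0},
        {"u_tp": 3.5},                       # barrier slope > 2 kT/rcu
        {"n_channels": 6, "drift": 0.9, "coop_drift": 0.3},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(cg.InvalidParameterError):
            cg.ModelParams(**kwargs)

    def test_roundtrip_dict(self):
        p = cg.ModelParams(n_channels=3, drift=-0.2, coop_drift=0.1, seed=9)
        assert cg.ModelParams.from_dict(p.to_dict()) == p


class TestSimulate:
    def test_same_seed_bit_identical(self, quick_params):
        t1, _ = cg.simulate(quick_params)
        t2, _ = cg.simulate(quick_params)
        assert np.array_equal(t1.values, t2.values)

    def test_different_seed_differs(self, quick_params):
        t1, _ = cg.simulate(quick_params)
        t2, _ = cg.simulate(quick_params.with_(seed=8))
        assert not np.array_equal(t1.values, t2.values)

    def test_levels_bounded_by_cluster_size(self):
        trace, _ = cg.simulate(cg.ModelParams(n_channels=5, n_dwells=2000,
                                              timescale_ratio=60, seed=3))
        assert set(np.unique(trace.values)) <= set(range(6))

    def test_dwell_count_exact(self, quick_params):
        trace, _ = cg.simulate(quick_params)
        assert len(cg.extract_dwells(trace)) == quick_params.n_dwells

    def test_kernel_matches_pure_python_reference(self):
        p = cg.ModelParams(n_channels=3, n_dwells=150, timescale_ratio=40,
                           b_max=8, coop_drift=-0.05, drift=0.2, seed=11)
        fast, _ = cg.simulate(p)
        ref, _ = simulate_reference(p)
        assert np.array_equal(fast.values, ref.values)

    def test_burn_in_changes_start_but_stays_deterministic(self, quick_params):
        p = quick_params.with_(burn_in_cycles=5)
        t1, _ = cg.simulate(p)
        t2, _ = cg.simulate(p)
        assert np.array_equal(t1.values, t2.values)
        t0, _ = cg.simulate(quick_params)
        assert not np.array_equal(t0.values, t1.values)

    def test_final_state_is_consistent(self, quick_params):
        trace, state = cg.simulate(quick_params)
        state.validate(quick_params)

    def test_single_channel_half_activation_symmetry(self):
        # open <-> closed is a symmetry at drift 0: P_open within 0.02 of 1/2
        trace, _ = cg.simulate(cg.ModelParams(n_channels=1, seed=17))
        assert abs(cg.relative_current(trace) - 0.5) < 0.02

    def test_initial_positions_avoid_threshold_and_boundaries(self):
        params = cg.ModelParams(n_channels=50, b_max=5)
        state = initial_state(params, np.random.default_rng(0))
        rc = state.rc_positions
        assert np.all(rc != 0) and np.all(rc > -5) and np.all(rc < 5)


class TestCooperationDirection:
    def test_mean_open_probability_ordering_at_half_activation(self):
        """Stronger positive cooperation raises, negative lowers, the mean
        per-channel open probability of a 4-channel cluster at drift 0."""
        res = {}
        for label in ("strong-positive", "weak-positive", "none", "negative"):
            cd = cg.COOPERATION_MODES[label].coop_drift
            vals = []
            for k in range(24):
                seed = cg.derive_seed(0, "coop-direction", label, k)
                trace, _ = cg.simulate(cg.ModelParams(
                    n_channels=4, coop_drift=cd, n_dwells=25_000, seed=seed))
                vals.append(cg.relative_current(trace))
            vals = np.asarray(vals)
            res[label] = (vals.mean(), vals.std(ddof=1) / np.sqrt(vals.size))
        order = ["strong-positive", "weak-positive", "none", "negative"]
        for hi, lo in zip(order[:-1], order[1:]):
            gap = res[hi][0] - res[lo][0]
            comb = np.hypot(res[hi][1], res[lo][1])
            assert gap > 3 * comb, (hi, lo, res)
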