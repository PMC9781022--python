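import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import floodkin as fk
from floodkin.errors import ParameterError
from floodkin.opes import OpesBiasState, excluded_beyond_abs, excluded_outside_interval


def fresh_state(**kw):
    defaults = dict(sigma=1.0, gamma=10.0, barrier=6.0, kt=1.0, pace=500,
                    deposit_interval=(-8.5, 8.5))
    defaults.update(kw)
    return OpesBiasState(**defaults)


class TestProbability:
    def test_empty_state_is_zero(self):
        st0 = fresh_state()
        assert st0.probability(0.7) == 0.0
        assert st0.energy(0.7) == 0.0

    def test_single_kernel_at_center(self):
        st1 = fresh_state()
        st1.update(0.0)
        assert st1.probability(0.0) == pytest.approx(1.0 / math.sqrt(2 * math.pi))

    def test_matches_brute_force_weighted_sum(self):
        centers = np.array([-1.0, 0.3, 2.2])
        weights = np.array([1.0, 2.5, 0.7])
        sigma = 0.8
        st3 = fresh_state(sigma=sigma, centers=centers, weights=weights, z_n=0.2)
        for s in (-2.0, 0.0, 1.7):
            brute = sum(
                w * math.exp(-0.5 * ((s - c) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
                for c, w in zip(centers, weights)
            ) / weights.sum()
            assert st3.probability(s) == pytest.approx(brute, rel=1e-12)


class TestUpdate:
    def test_first_kernel_has_unit_weight(self):
        st1 = fresh_state()
        st1.update(0.3)
        assert st1.weights == pytest.approx([1.0])

    def test_deposition_skipped_in_excluded_region(self):
        st1 = fresh_state(deposit_interval=excluded_beyond_abs(8.5))
        st1.update(9.0)
        st1.update(-8.6)
        assert st1.n_kernels == 0
        st1.update(8.4)
        assert st1.n_kernels == 1

    def test_second_update_weight_matches_hand_computation(self):
        st1 = fresh_state()
        st1.update(0.0)
        # hand computation: one kernel at 0 => P(0) = G(0,0), Z = P(0), ratio 1
        # saturated ratio => V_1(0) = (1-1/gamma) kT log((1+eps)/eps)
        pref = (1 - 1 / st1.gamma) * st1.kt
        eps = math.exp(-st1.barrier / pref)
        v1_hand = pref * math.log((1 + eps) / eps)
        assert st1.energy(0.0) == pytest.approx(v1_hand, rel=1e-12)
        st1.update(0.0)
        assert st1.weights[-1] == pytest.approx(math.exp(v1_hand / st1.kt), rel=1e-12)
        assert st1.weights[-1] > 1.0

    def test_functional_update_leaves_input_unchanged(self):
        st1 = fresh_state()
        st2 = fk.opes_update(st1, 0.5)
        assert st1.n_kernels == 0
        assert st2.n_kernels == 1


class TestBiasEnergy:
    def test_ratio_equal_epsilon_gives_prefactor_log2(self):
        st1 = fresh_state(centers=np.array([0.0]), weights=np.array([1.0]), z_n=1.0)
        from scipy.optimize import brentq

        target = st1.epsilon * st1.z_n  # P(s) such that P/Z = eps
        s_eps = brentq(lambda s: st1.probability(s) - target, 0.0, 40.0)
        assert st1.energy(s_eps) == pytest.approx(
            st1.prefactor * math.log(2.0), rel=1e-9
        )

    def test_gamma_limit_recovers_static_mixture_form(self):
        st1 = fresh_state(
            gamma=1e6, barrier=5.0, sigma=0.7,
            centers=np.array([-1.0, 0.5]), weights=np.array([1.0, 2.0]), z_n=0.4,
        )
        grid = np.linspace(-3, 3, 41)
        r = np.minimum(st1.probability(grid) / st1.z_n, 1.0)
        eps = math.exp(-5.0)  # gamma -> inf: eps -> e^{-barrier/kT}
        reference = np.log1p(r / eps)  # kT log((r + eps)/eps)
        np.testing.assert_allclose(st1.energy(grid), reference, rtol=0, atol=2e-5)

    @given(
        st.lists(st.floats(-8.0, 8.0), min_size=1, max_size=12),
        st.floats(0.05, 2.0),
        st.floats(-9.0, 9.0),
    )
    def test_bias_bounds_hold_for_arbitrary_states(self, centers, sigma, s):
        state = fresh_state(sigma=sigma, centers=np.array(centers),
                            weights=np.ones(len(centers)))
        state.z_n = float(np.mean(state.probability(state.centers)))
        v = state.energy(s)
        assert 0.0 <= v <= state.max_energy_bound + 1e-9

    def test_gradient_matches_finite_difference(self):
        state = fresh_state(sigma=0.5, centers=np.array([-1.0, 0.2, 1.4]),
                            weights=np.array([1.0, 3.0, 2.0]))
        state.z_n = 0.8
        for s in np.linspace(-3, 3, 25):
            if state.probability(s) / state.z_n > 0.95:
                continue  # skip the saturated plateau edge
            fd = (state.energy(s + 1e-6) - state.energy(s - 1e-6)) / 2e-6
            assert state.gradient(s) == pytest.approx(fd, rel=1e-4, abs=1e-8)


@pytest.fixture(scope="module")
def flooding_run(double_well_8kt):
    scen = double_well_8kt
    bias = OpesBiasState(
        sigma=0.06, gamma=10.0, barrier=6.0, kt=1.0, pace=500,
        deposit_interval=excluded_outside_interval(scen.surface.domain[0], -0.5),
    )
    traj = fk.simulate(
        scen, bias, fk.SimulationParams(dt=1e-3, max_steps=400_000, seed=77),
    )
    return bias, traj


class TestEngineIntegration:
    def test_no_kernel_in_excluded_region(self, flooding_run):
        bias, traj = flooding_run
        assert traj.escaped
        lo, hi = bias.deposit_interval
        assert np.all((bias.centers >= lo) & (bias.centers <= hi))

    def test_flooding_leaves_threshold_unbiased(self, flooding_run, double_well_8kt):
        bias, traj = flooding_run
        v_thr = bias.energy(double_well_8kt.absorbing_threshold)
        assert v_thr < 0.01 * bias.barrier

    def test_biased_updates_are_reproducible(self, double_well_8kt):
        def run():
            bias = OpesBiasState(
                sigma=0.06, gamma=10.0, barrier=6.0, kt=1.0, pace=500,
                deposit_interval=(double_well_8kt.surface.domain[0], -0.5),
            )
            traj = fk.simulate(
                double_well_8kt, bias,
                fk.SimulationParams(dt=1e-3, max_steps=50_000, seed=78),
            )
            return bias, traj

        b1, t1 = run()
        b2, t2 = run()
        assert np.array_equal(b1.centers, b2.centers)
        assert np.array_equal(b1.weights, b2.weights)
        assert np.array_equal(t1.cv_values, t2.cv_values)


def test_json_round_trip():
    state = fresh_state(centers=np.array([0.1, -0.4]), weights=np.array([1.0, 2.0]))
    state.z_n = 0.33
    rebuilt = OpesBiasState.from_json(state.to_json())
    grid = np.linspace(-2, 2, 50)
    np.testing.assert_allclose(rebuilt.energy(grid), state.energy(grid), rtol=1e-12)


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterError):
        fresh_state(sigma=0.0)
    with pytest.raises(ParameterError):
        fresh_state(gamma=1.0)
    with pytest.raises(ParameterError):
        excluded_outside_interval(2.0, -2.0)
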