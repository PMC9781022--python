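import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import floodkin as fk
from floodkin.errors import ContractError, DataError, ParameterError, StateError


def make_traj(bias_values, dt=1.0, escaped=True):
    n = len(bias_values)
    return fk.Trajectory(
        times=np.arange(1, n + 1) * dt,
        cv_values=np.zeros(n),
        bias_values=np.asarray(bias_values, dtype=float),
        seed=0,
        escaped=escaped,
        escape_step=n if escaped else None,
    )


class TestRescaleTime:
    def test_zero_bias_identity(self):
        ev = fk.rescale_time(make_traj([0.0, 0.0, 0.0], dt=1 / 3), kt=1.0)
        assert ev.acceleration == 1.0
        assert ev.physical_time == ev.apparent_time == 1.0

    def test_constant_bias_closed_form(self):
        ev = fk.rescale_time(make_traj([2.0] * 4, dt=0.25), kt=1.0)
        assert ev.acceleration == pytest.approx(math.e ** 2, rel=1e-12)
        assert ev.physical_time == pytest.approx(math.e ** 2, rel=1e-12)

    def test_recorded_series_direct_summation(self):
        # series {0, 1, 2} kT over 3 unit steps: tau = e^0 + e^1 + e^2
        ev = fk.rescale_time(make_traj([0.0, 1.0, 2.0], dt=1.0), kt=1.0)
        assert ev.physical_time == pytest.approx(1 + math.e + math.e ** 2, rel=1e-12)

    def test_unescaped_rejected(self):
        with pytest.raises(StateError):
            fk.rescale_time(make_traj([0.0, 0.0], escaped=False), kt=1.0)

    def test_negative_bias_rejected(self):
        with pytest.raises(ContractError):
            fk.rescale_time(make_traj([0.0, -0.5]), kt=1.0)


class TestFitExitTimes:
    def test_moments_by_hand(self):
        tau, mu, sigma = fk.fit_exit_times([1.0, 2.0, 3.0])
        assert mu == 2.0
        assert sigma == 1.0
        assert tau > 0

    def test_consistency_on_exponential_draws(self):
        rng = np.random.default_rng(7)
        draws = rng.exponential(5.0, 5000)
        tau, mu, sigma = fk.fit_exit_times(draws)
        assert abs(tau - 5.0) < 3 * 5.0 / math.sqrt(5000)

    def test_degenerate_equal_times_finite(self):
        tau, mu, sigma = fk.fit_exit_times([2.0] * 10)
        assert sigma == 0.0
        assert np.isfinite(tau) and tau > 0

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -2.0], [0.0, 1.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(DataError):
            fk.fit_exit_times(bad)


class TestKsPoissonCheck:
    def test_exact_exponential_quantiles_fit_perfectly(self):
        n, tau = 25, 3.0
        q = tau * np.log(n / (n - np.arange(1, n + 1) + 0.5))
        ks, p = fk.ks_poisson_test(q, tau)
        assert ks < 0.05
        assert p > 0.99

    def test_identical_times_strongly_rejected(self):
        times = np.full(25, 2.0)
        tau, _, _ = fk.fit_exit_times(times)
        ks, p = fk.ks_poisson_test(times, tau)
        assert p < 1e-6

    def test_too_few_events_rejected(self):
        with pytest.raises(DataError, match="more"):
            fk.ks_poisson_test([1.0, 2.0, 3.0], 2.0)

    def test_bootstrap_p_value_is_probability(self):
        rng = np.random.default_rng(8)
        draws = rng.exponential(2.0, 25)
        tau, _, _ = fk.fit_exit_times(draws)
        ks, p = fk.ks_poisson_test(draws, tau, n_bootstrap=100, seed=1)
        assert 0.0 < p <= 1.0


class TestSummaries:
    def test_rate_is_reciprocal_of_tau(self):
        rng = np.random.default_rng(9)
        summary = fk.summarize(rng.exponential(4.0, 50))
        assert summary.rate * summary.tau_fit == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= summary.p_value <= 1.0

    def test_unbiased_ensemble_has_unit_acceleration(self, shipped_scenarios):
        scen = shipped_scenarios["interlayer_edge"]
        summary, table = fk.run_escape_ensemble(
            scen, "unbiased", n_runs=6, base_seed=900,
            params=fk.SimulationParams(dt=1e-3, max_steps=300_000),
        )
        assert summary.censored == 0
        assert np.all(table["acceleration"].to_numpy() == 1.0)
        # zero-bias identity: rescaled tau_fit equals raw-time tau_fit exactly
        raw_tau, _, _ = fk.fit_exit_times(table["t_md"].to_numpy())
        assert summary.tau_fit == pytest.approx(raw_tau, rel=1e-12)

    def test_censoring_reported_and_warned(self, shipped_scenarios):
        scen = shipped_scenarios["surface_desorption"]
        with pytest.warns(UserWarning, match="censored"):
            summary, _ = fk.run_escape_ensemble(
                scen, "unbiased", n_runs=25, base_seed=901,
                params=fk.SimulationParams(dt=1e-3, max_steps=30_000),
            )
        assert summary.censored > 5
        assert summary.n_events + summary.censored == 25

    def test_unknown_method_rejected(self, shipped_scenarios):
        with pytest.raises(ParameterError):
            fk.run_escape_ensemble(shipped_scenarios["interlayer_edge"], "abf", 5, 0)


class TestDiffusionEstimate:
    def test_worked_two_depth_example(self):
        # two release depths 4.0 A apart, times 54.4 us and 200.0 us
        est = fk.estimate_diffusion(y1=4.0e-8, t1=54.4e-6, y2=0.0, t2=200.0e-6)
        assert est.d == pytest.approx(1.10e-11, rel=0.01)  # cm^2/s

    def test_equal_positions_give_zero(self):
        assert fk.estimate_diffusion(1.0, 0.0, 1.0, 2.0).d == 0.0

    def test_time_ordering_enforced(self):
        with pytest.raises(ParameterError):
            fk.estimate_diffusion(0.0, 2.0, 1.0, 2.0)

    @given(
        st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0, 1e3), st.floats(1e-6, 1e3),
    )
    def test_identity_on_randomized_inputs(self, y1, y2, t1, gap):
        est = fk.estimate_diffusion(y1, t1, y2, t1 + gap)
        assert est.d * (est.t2 - est.t1) == pytest.approx((y2 - y1) ** 2, rel=1e-12, abs=1e-300)
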