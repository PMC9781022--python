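import json
from pathlib import Path

import numpy as np
import pytest

import floodkin as fk
from floodkin.errors import ParameterError


class TestBuildScenario:
    def test_start_positions_follow_geometry(self, shipped_scenarios):
        assert shipped_scenarios["interlayer_center"].start_position == 0.0
        assert shipped_scenarios["interlayer_mid"].start_position == 3.0
        assert shipped_scenarios["interlayer_edge"].start_position == 5.8
        # same surface for all three interlayer geometries
        grid = np.linspace(-8, 8, 30)
        np.testing.assert_array_equal(
            shipped_scenarios["interlayer_center"].surface.energy(grid),
            shipped_scenarios["interlayer_edge"].surface.energy(grid),
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ParameterError):
            fk.build_scenario("bulk_solution")

    def test_overrides_apply(self):
        scen = fk.build_scenario("interlayer_mid", start_position=2.0)
        assert scen.start_position == 2.0

    def test_ground_truth_ordering(self, shipped_scenarios):
        t = {k: fk.ground_truth(v).mfpt for k, v in shipped_scenarios.items()
             if k.startswith("interlayer")}
        assert t["interlayer_center"] > t["interlayer_mid"] > t["interlayer_edge"]

    def test_surface_desorption_is_fast(self, shipped_scenarios):
        """All ten unbiased desorption runs escape well within the step budget."""
        scen = shipped_scenarios["surface_desorption"]
        assert fk.ground_truth(scen).mfpt < 100.0  # 1e5 steps at dt = 1e-3
        for i in range(10):
            traj = fk.simulate(
                scen, None,
                fk.SimulationParams(dt=1e-3, max_steps=1_000_000, seed=600 + i,
                                    record_stride=100_000),
            )
            assert traj.escaped


class TestFixtures:
    def test_zero_bias_round_trip_recovers_tau(self, tmp_path):
        true_tau = 5.0
        n = 1000
        spec = fk.FixtureSpec(n_runs=n, true_tau=true_tau, bias_profile="zero",
                              seed=21, dt=0.05)
        paths = fk.generate_fixture(spec, tmp_path)
        events = [fk.rescale_time(fk.read_colvar(p), kt=1.0) for p in paths]
        assert all(e.acceleration == 1.0 for e in events)
        tau_fit, _, _ = fk.fit_exit_times([e.physical_time for e in events])
        assert abs(tau_fit - true_tau) < 3 * true_tau / np.sqrt(n)

    def test_constant_bias_acceleration_exact(self, tmp_path):
        spec = fk.FixtureSpec(n_runs=50, true_tau=5.0, bias_profile="constant",
                              v0=3.0, seed=22, dt=0.01)
        paths = fk.generate_fixture(spec, tmp_path)
        events = [fk.rescale_time(fk.read_colvar(p), kt=1.0) for p in paths]
        for e in events:
            assert e.acceleration == pytest.approx(np.exp(3.0), rel=1e-12)
        tau_fit, _, _ = fk.fit_exit_times([e.physical_time for e in events])
        assert abs(tau_fit - 5.0) < 3 * 5.0 / np.sqrt(50) + 0.05

    def test_sampled_profile_round_trip(self, tmp_path):
        true_tau = 40.0
        n = 200
        spec = fk.FixtureSpec(n_runs=n, true_tau=true_tau,
                              bias_profile="sampled-from-run", seed=23, dt=0.01)
        paths = fk.generate_fixture(spec, tmp_path)
        events = [fk.rescale_time(fk.read_colvar(p), kt=1.0) for p in paths]
        # early segments of the replayed flooding trace are unbiased, so
        # very fast draws can legitimately have acceleration exactly 1
        assert all(e.acceleration >= 1.0 for e in events)
        assert max(e.acceleration for e in events) > 1.0
        tau_fit, _, _ = fk.fit_exit_times([e.physical_time for e in events])
        assert abs(tau_fit - true_tau) < 3 * true_tau / np.sqrt(n) + 0.6

    def test_manifest_and_byte_determinism(self, tmp_path):
        spec = fk.FixtureSpec(n_runs=4, true_tau=2.0, seed=24, dt=0.01)
        paths = fk.generate_fixture(spec, tmp_path / "a")
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest["run_seeds"] == [24, 25, 26, 27]
        assert manifest["true_tau"] == 2.0
        fk.generate_fixture(spec, tmp_path / "b")
        for p in paths:
            other = tmp_path / "b" / Path(p).name
            assert Path(p).read_bytes() == other.read_bytes()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            fk.FixtureSpec(n_runs=0, true_tau=1.0)
        with pytest.raises(ParameterError):
            fk.FixtureSpec(n_runs=1, true_tau=-1.0)
        with pytest.raises(ParameterError):
            fk.FixtureSpec(n_runs=1, true_tau=1.0, bias_profile="ramp")
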