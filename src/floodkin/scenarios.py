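"""Shipped release scenarios and COLVAR-style fixture generation.

Four scenarios mirror the geometries a drug can occupy in a layered
excipient: starting at the interlayer midpoint, half-way to the layer
edge, at the edge, and adsorbed on the outer surface (fast desorption).
All are desk-scale surrogates with exact ground truth attached via the
MFPT oracle; the release-time ordering T(center) > T(mid) > T(edge) of
the real system is preserved by construction.

``generate_fixture`` writes COLVAR-dialect files whose rescaled exit
times are, by construction, draws from an exponential distribution with a
known mean -- the null hypothesis the KS check tests -- so analysis bugs
can be separated from dynamics bugs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colvar import write_colvar_arrays
from .errors import ParameterError
from .oracle import OracleResult, scenario_mfpt
from .surfaces import (
    SCENARIO_LABELS,
    ScenarioSpec,
    make_double_well,
    make_interlayer_surrogate,
    make_single_well,
)

# Shipped surrogate defaults: 4 kT binding-site corrugation with unit
# period, layer edge at 6, 2 kT solvation drop over unit width; barriers
# low enough that the oracle and brute-force runs stay desk-scale while
# preserving the center >> mid >> edge release-time ordering.
INTERLAYER_DEFAULTS = dict(
    corrugation_depth=4.0,
    corrugation_period=1.0,
    edge_position=6.0,
    solvation_drop=2.0,
    edge_width=1.0,
)
SURFACE_WELL_DEPTH = 3.0
ABSORBING_THRESHOLD = 8.5  # first touch of |y| >= 8.5 counts as released
START_POSITIONS = {
    "interlayer_center": 0.0,
    "interlayer_mid": 3.0,
    "interlayer_edge": 5.8,
}


def build_scenario(label: str, **overrides) -> ScenarioSpec:
    """Shipped parameterization for one of the four release scenarios."""
    if label not in SCENARIO_LABELS:
        raise ParameterError(f"unknown scenario label {label!r}; choose from {SCENARIO_LABELS}")
    surface_overrides = overrides.pop("surface_params", {})
    if label == "surface_desorption":
        depth = surface_overrides.pop("depth", SURFACE_WELL_DEPTH)
        surface = make_single_well(depth=depth, **surface_overrides)
        spec = ScenarioSpec(
            surface=surface,
            start_position=0.0,
            absorbing_threshold=4.0,
            label=label,
            two_sided=True,
            bound_region=(-2.0, 2.0),
        )
    else:
        params = {**INTERLAYER_DEFAULTS, **surface_overrides}
        surface = make_interlayer_surrogate(**params)
        edge = params["edge_position"]
        spec = ScenarioSpec(
            surface=surface,
            start_position=START_POSITIONS[label],
            absorbing_threshold=ABSORBING_THRESHOLD,
            label=label,
            two_sided=True,
            bound_region=(-edge, edge),
        )
    if overrides:
        spec = spec.with_overrides(**overrides)
    return spec


def double_well_scenario(
    barrier_height: float,
    well_separation: float = 2.0,
    temperature_kt: float = 1.0,
    d0: float = 1.0,
) -> ScenarioSpec:
    """Validation scenario: start in the left well, absorb past the right minimum."""
    surface = make_double_well(barrier_height, well_separation)
    a = well_separation / 2.0
    return ScenarioSpec(
        surface=surface,
        start_position=-a,
        absorbing_threshold=a,
        label="double_well",
        temperature_kt=temperature_kt,
        diffusion_coefficient_d0=d0,
        two_sided=False,
        bound_region=(surface.domain[0], 0.0),
    )


def ground_truth(scenario: ScenarioSpec) -> OracleResult:
    """Oracle MFPT attached to a shipped scenario."""
    return scenario_mfpt(scenario)


# ---------------------------------------------------------------------------
# fixtures

BIAS_PROFILES = ("zero", "constant", "sampled-from-run")


@dataclass(frozen=True)
class FixtureSpec:
    """Design of a synthetic COLVAR ensemble with known true tau."""

    n_runs: int
    true_tau: float
    bias_profile: str = "zero"
    v0: float = 0.0  # constant-profile bias level, kT units
    seed: int = 0
    dt: float = 1e-3
    kt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ParameterError("n_runs must be >= 1")
        if self.true_tau <= 0:
            raise ParameterError("true_tau must be positive")
        if self.bias_profile not in BIAS_PROFILES:
            raise ParameterError(f"bias_profile must be one of {BIAS_PROFILES}")
        if self.bias_profile == "constant" and self.v0 < 0:
            raise ParameterError("constant bias level must be >= 0")


def _sampled_bias_series(spec: FixtureSpec) -> np.ndarray:
    """Bias series taken from a real flooding run on the double well.

    One short seeded OPES run provides an authentic saturating bias trace
    that is replayed (cyclically) when building fixture files.
    """
    from .engine import SimulationParams, simulate
    from .opes import OpesBiasState

    scen = double_well_scenario(6.0)
    bias = OpesBiasState(
        sigma=0.06, gamma=10.0, barrier=4.0, kt=spec.kt, pace=100,
        deposit_interval=(scen.surface.domain[0], -0.5),
    )
    traj = simulate(
        scen, bias,
        SimulationParams(dt=spec.dt, max_steps=20_000, seed=spec.seed + 55_000,
                         record_stride=1),
    )
    return np.asarray(traj.bias_values, dtype=float)


def generate_fixture(spec: FixtureSpec, output_directory) -> list[Path]:
    """Write ``n_runs`` COLVAR files plus a manifest; deterministic in seed.

    Each file's rescaled exit time (acceleration x apparent time, with the
    acceleration computed from the recorded bias column exactly as the
    analysis pipeline does) is an exponential draw with mean ``true_tau``:
    a physical time is drawn first, then the apparent duration is found by
    accumulating e^{V/kT} dt along the bias profile until the physical
    clock reaches the draw.
    """
    outdir = Path(output_directory)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    if spec.bias_profile == "sampled-from-run":
        base_series = _sampled_bias_series(spec)
    paths: list[Path] = []
    run_seeds: list[int] = []
    for i in range(spec.n_runs):
        run_seed = spec.seed + i
        run_seeds.append(run_seed)
        t_phys = float(np.random.default_rng(run_seed).exponential(spec.true_tau))
        if spec.bias_profile == "zero":
            n_steps = max(1, int(np.ceil(t_phys / spec.dt)))
            bias = np.zeros(n_steps + 1)
        elif spec.bias_profile == "constant":
            acc = float(np.exp(spec.v0 / spec.kt))
            n_steps = max(1, int(np.ceil(t_phys / (acc * spec.dt))))
            bias = np.full(n_steps + 1, spec.v0)
        else:
            # accumulate rescaled time along the replayed bias trace
            increments = np.exp(base_series / spec.kt) * spec.dt
            clock = np.cumsum(np.tile(increments, int(np.ceil(t_phys / increments.sum())) + 1))
            n_steps = max(1, int(np.searchsorted(clock, t_phys) + 1))
            reps = int(np.ceil((n_steps + 1) / len(base_series)))
            bias = np.tile(base_series, reps)[: n_steps + 1]
        times = np.arange(n_steps + 1) * spec.dt
        cv = np.linspace(0.0, 1.0, n_steps + 1)  # placeholder monotone CV track
        path = outdir / f"run_{i:04d}.colvar"
        write_colvar_arrays(path, times, cv, bias)
        paths.append(path)
    manifest = {
        "n_runs": spec.n_runs,
        "true_tau": spec.true_tau,
        "bias_profile": spec.bias_profile,
        "v0": spec.v0,
        "seed": spec.seed,
        "dt": spec.dt,
        "kt": spec.kt,
        "run_seeds": run_seeds,
        "files": [p.name for p in paths],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
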