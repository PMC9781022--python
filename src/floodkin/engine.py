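"""Overdamped Langevin (Brownian) dynamics on a surface plus optional bias.

Euler--Maruyama update:

    y_{n+1} = y_n - (D0/kT) * d(U+V)/dy (y_n) * dt + sqrt(2 D0 dt) * xi_n

with xi_n standard normal from one seeded generator per run.  Reflecting
domain boundaries are enforced by position mirroring.  The run ends at the
first touch of the scenario's absorbing threshold or at ``max_steps``.

The recorded time series carries the instantaneous bias at the visited
point at each recorded step, which is what the hyperdynamics time
rescaling averages over; biased production runs should therefore use
``record_stride=1``.

A bias evaluator is any object with ``energy(y)`` and ``gradient(y)``;
an evolving bias (OPES flooding) may additionally expose
``on_step(y, step)``, called after every engine step so it can deposit
kernels at its own pace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import IntegrationError, ParameterError
from .surfaces import ScenarioSpec

_NOISE_BLOCK = 8192


@dataclass(frozen=True)
class SimulationParams:
    """Integrator settings. ``noise_factor=0`` disables thermal noise (tests)."""

    dt: float = 1e-3
    max_steps: int = 1_000_000
    kt: float = 1.0
    d0: float = 1.0
    seed: int = 0
    record_stride: int = 1
    noise_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be >= 1")
        if self.kt <= 0 or self.d0 <= 0:
            raise ParameterError("kT and D0 must be positive")
        if self.record_stride < 1:
            raise ParameterError("record_stride must be >= 1")


@dataclass
class Trajectory:
    """Recorded time series of one run (times strictly increasing)."""

    times: np.ndarray
    cv_values: np.ndarray
    bias_values: np.ndarray
    seed: int
    escaped: bool
    escape_step: int | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.cv_values) == len(self.bias_values) == n):
            raise ParameterError("times/cv/bias must have equal lengths")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")

    @property
    def escape_time(self) -> float:
        if not self.escaped:
            raise ParameterError("trajectory did not escape")
        return float(self.times[-1])


def _reflect(y: float, lo: float, hi: float) -> float:
    # mirror until inside; at sane dt a single reflection suffices
    while y < lo or y > hi:
        if y < lo:
            y = 2.0 * lo - y
        else:
            y = 2.0 * hi - y
    return y


def simulate(scenario: ScenarioSpec, bias, params: SimulationParams) -> Trajectory:
    """Propagate one run. Identical inputs give a bit-identical trajectory."""
    surface = scenario.surface
    lo, hi = surface.domain
    dt = params.dt
    mob = params.d0 / params.kt * dt
    sig = params.noise_factor * math.sqrt(2.0 * params.d0 * dt)
    rng = np.random.default_rng(params.seed)
    grad_u = surface.gradient_fn
    has_bias = bias is not None
    on_step = getattr(bias, "on_step", None) if has_bias else None

    y = float(scenario.start_position)
    rec_t: list[float] = []
    rec_y: list[float] = []
    rec_v: list[float] = []

    def record(step: int, ynow: float) -> None:
        rec_t.append(step * dt)
        rec_y.append(ynow)
        rec_v.append(float(bias.energy(ynow)) if has_bias else 0.0)

    record(0, y)
    escaped = False
    escape_step: int | None = None
    noise = rng.standard_normal(_NOISE_BLOCK)
    n_noise = 0

    for step in range(1, params.max_steps + 1):
        f = -float(grad_u(y))
        if has_bias:
            f -= float(bias.gradient(y))
        if not math.isfinite(f):
            raise IntegrationError(f"non-finite force at step {step} (y={y!r})")
        if n_noise == _NOISE_BLOCK:
            noise = rng.standard_normal(_NOISE_BLOCK)
            n_noise = 0
        y = y + mob * f + sig * noise[n_noise]
        n_noise += 1
        y = _reflect(y, lo, hi)

        if scenario.escaped(y):
            record(step, y)
            escaped = True
            escape_step = step
            break
        if step % params.record_stride == 0:
            record(step, y)
        if on_step is not None:
            on_step(y, step)

    return Trajectory(
        times=np.asarray(rec_t),
        cv_values=np.asarray(rec_y),
        bias_values=np.asarray(rec_v),
        seed=params.seed,
        escaped=escaped,
        escape_step=escape_step,
        dt=dt,
    )


def sample_bound_state(
    scenario: ScenarioSpec,
    n_steps: int,
    seed: int,
    params: SimulationParams | None = None,
    subsample: int = 10,
) -> np.ndarray:
    """Unbiased sampling of the bound state, confined to ``bound_region``.

    The guest is reflected at the bound-region edges so the sample never
    contaminates the product side; used to fit the GAMBES mixture and to
    set the OPES kernel bandwidth.
    """
    if params is None:
        params = SimulationParams(seed=seed)
    region = scenario.bound_region or scenario.surface.domain
    lo = max(region[0], scenario.surface.domain[0])
    hi = min(region[1], scenario.surface.domain[1])
    confined = ScenarioSpec(
        surface=scenario.surface,
        start_position=scenario.start_position,
        absorbing_threshold=float("inf"),
        label=scenario.label,
        temperature_kt=scenario.temperature_kt,
        diffusion_coefficient_d0=scenario.diffusion_coefficient_d0,
        two_sided=True,
        bound_region=(lo, hi),
    )

    dt = params.dt
    mob = params.d0 / params.kt * dt
    sig = math.sqrt(2.0 * params.d0 * dt)
    rng = np.random.default_rng(seed)
    grad_u = confined.surface.gradient_fn
    y = float(scenario.start_position)
    out = np.empty(n_steps // subsample)
    k = 0
    noise = rng.standard_normal(_NOISE_BLOCK)
    n_noise = 0
    for step in range(1, n_steps + 1):
        if n_noise == _NOISE_BLOCK:
            noise = rng.standard_normal(_NOISE_BLOCK)
            n_noise = 0
        y = y - mob * float(grad_u(y)) + sig * noise[n_noise]
        n_noise += 1
        y = _reflect(y, lo, hi)
        if step % subsample == 0 and k < len(out):
            out[k] = y
            k += 1
    return out[:k]
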