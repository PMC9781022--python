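"""One-dimensional potential-energy surfaces and release scenarios.

The collective variable is the coordinate y of the guest molecule along the
release direction (reduced length units; energies in kT).  Two families of
surfaces are shipped:

* a quartic double well, the standard validation landscape for flooding
  methods, where the exact mean first-passage time is available from
  quadrature; and
* a clay-interlayer surrogate: periodic corrugation wells standing in for
  the discrete binding sites a drug visits while diffusing between clay
  layers, terminated by a smooth solvation drop at the layer edge, beyond
  which the potential is flat (solvent).

A :class:`ScenarioSpec` bundles a surface with a start position, an
absorbing threshold (escape = first touch, no commitment window), the
temperature and the bare diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping

import numpy as np
from scipy.special import expit

from .errors import ParameterError

BoundaryKind = Literal["reflecting", "absorbing", "open"]

SCENARIO_LABELS = (
    "interlayer_center",
    "interlayer_mid",
    "interlayer_edge",
    "surface_desorption",
)


@dataclass(frozen=True)
class PotentialSurface:
    """Evaluable energy/gradient on a closed 1D domain.

    ``energy_fn``/``gradient_fn`` must accept floats and numpy arrays.
    Energies are in kT units by default, lengths in reduced units.
    """

    name: str
    params: Mapping[str, float]
    domain: tuple[float, float]
    energy_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    gradient_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    boundary: tuple[BoundaryKind, BoundaryKind] = ("reflecting", "reflecting")

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not (lo < hi):
            raise ParameterError(f"domain must be an increasing interval, got {self.domain}")

    def energy(self, y):
        return self.energy_fn(np.asarray(y, dtype=float))

    def gradient(self, y):
        return self.gradient_fn(np.asarray(y, dtype=float))

    # -- serialization ------------------------------------------------
    def to_toml(self) -> str:
        """Render the surface as a TOML block (factory name + parameters)."""
        from .config import dumps_table

        return dumps_table(
            "surface",
            {"name": self.name, **{k: float(v) for k, v in self.params.items()}},
        )

    @staticmethod
    def from_params(name: str, params: Mapping[str, float]) -> "PotentialSurface":
        """Rebuild a shipped surface from its factory name and parameters."""
        factories = {
            "double_well": make_double_well,
            "interlayer_surrogate": make_interlayer_surrogate,
            "single_well": make_single_well,
        }
        if name not in factories:
            raise ParameterError(f"unknown surface factory {name!r}")
        return factories[name](**params)


def make_double_well(barrier_height: float, well_separation: float) -> PotentialSurface:
    """Quartic double well U(y) = B (1 - (y/a)^2)^2 with a = separation/2.

    Minima (U = 0) at +-a, barrier of height B at y = 0.
    """
    if barrier_height <= 0 or well_separation <= 0:
        raise ParameterError("barrier_height and well_separation must be positive")
    b = float(barrier_height)
    a = float(well_separation) / 2.0

    def energy(y):
        r = 1.0 - (y / a) ** 2
        return b * r * r

    def gradient(y):
        return -4.0 * b * y * (1.0 - (y / a) ** 2) / (a * a)

    return PotentialSurface(
        name="double_well",
        params={"barrier_height": b, "well_separation": 2 * a},
        domain=(-2.0 * a, 2.0 * a),
        energy_fn=energy,
        gradient_fn=gradient,
    )


def make_interlayer_surrogate(
    corrugation_depth: float,
    corrugation_period: float,
    edge_position: float,
    solvation_drop: float,
    edge_width: float,
) -> PotentialSurface:
    """Clay-interlayer surrogate, even in y (two symmetric exits).

    Inside |y| <= edge_position the guest hops between periodic binding
    sites, U = depth * sin^2(pi y / period) (mimicking the silicon-carbonyl
    contact sites).  Past the layer edge the potential descends smoothly
    (logistic switch over ``edge_width``) by ``solvation_drop`` and is flat
    in the solvent.  Continuous and differentiable everywhere.
    """
    for nm, v in (
        ("corrugation_depth", corrugation_depth),
        ("corrugation_period", corrugation_period),
        ("edge_position", edge_position),
        ("solvation_drop", solvation_drop),
        ("edge_width", edge_width),
    ):
        if v <= 0:
            raise ParameterError(f"{nm} must be positive, got {v}")
    if edge_position <= corrugation_period:
        raise ParameterError("edge_position must exceed corrugation_period")

    depth = float(corrugation_depth)
    period = float(corrugation_period)
    edge = float(edge_position)
    drop = float(solvation_drop)
    width = float(edge_width)
    y_c = edge + width / 2.0  # switch midpoint
    lam = width / 8.0  # logistic scale: descent essentially complete over edge_width

    def _switch(ay):
        return expit((ay - y_c) / lam)

    def energy(y):
        ay = np.abs(y)
        s = _switch(ay)
        corr = depth * np.sin(np.pi * y / period) ** 2
        return corr * (1.0 - s) - drop * s

    def gradient(y):
        ay = np.abs(y)
        s = _switch(ay)
        corr = depth * np.sin(np.pi * y / period) ** 2
        dcorr = depth * (np.pi / period) * np.sin(2.0 * np.pi * y / period)
        ds = s * (1.0 - s) / lam * np.sign(y)  # d s / d y
        return dcorr * (1.0 - s) - (corr + drop) * ds

    half_domain = y_c + 6.0 * width
    return PotentialSurface(
        name="interlayer_surrogate",
        params={
            "corrugation_depth": depth,
            "corrugation_period": period,
            "edge_position": edge,
            "solvation_drop": drop,
            "edge_width": width,
        },
        domain=(-half_domain, half_domain),
        energy_fn=energy,
        gradient_fn=gradient,
    )


def make_single_well(depth: float, width: float = 1.0, flat_extent: float = 6.0) -> PotentialSurface:
    """Gaussian binding well of given depth: the fast surface-desorption case.

    U(y) = -depth * exp(-y^2 / (2 width^2)), flat (solvent) far from the well.
    """
    if depth <= 0 or width <= 0 or flat_extent <= 0:
        raise ParameterError("depth, width and flat_extent must be positive")
    d = float(depth)
    w = float(width)

    def energy(y):
        return -d * np.exp(-(y * y) / (2.0 * w * w))

    def gradient(y):
        return d * y / (w * w) * np.exp(-(y * y) / (2.0 * w * w))

    return PotentialSurface(
        name="single_well",
        params={"depth": d, "width": w, "flat_extent": float(flat_extent)},
        domain=(-float(flat_extent), float(flat_extent)),
        energy_fn=energy,
        gradient_fn=gradient,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """A release scenario: surface + start + absorbing threshold + bath.

    Escape is the first touch of the absorbing threshold: |y| >= threshold
    when ``two_sided`` (the interlayer has two symmetric exits), else
    y >= threshold (one-sided, used for the double-well validation case).
    ``bound_region`` is the interval the guest is confined to (by
    reflection) when sampling the bound state for bias construction.
    """

    surface: PotentialSurface
    start_position: float
    absorbing_threshold: float
    label: str
    temperature_kt: float = 1.0
    diffusion_coefficient_d0: float = 1.0
    two_sided: bool = True
    bound_region: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.temperature_kt <= 0 or self.diffusion_coefficient_d0 <= 0:
            raise ParameterError("temperature and D0 must be positive")
        lo, hi = self.surface.domain
        if not (lo < self.start_position < hi):
            raise ParameterError("start_position must lie strictly inside the domain")
        start = abs(self.start_position) if self.two_sided else self.start_position
        if start >= self.absorbing_threshold:
            raise ParameterError("start_position must be below the absorbing threshold")

    def escaped(self, y: float) -> bool:
        if self.two_sided:
            return abs(y) >= self.absorbing_threshold
        return y >= self.absorbing_threshold

    def with_overrides(self, **overrides) -> "ScenarioSpec":
        return replace(self, **overrides)

    def to_toml(self) -> str:
        from .config import dumps_table

        block = {
            "label": self.label,
            "start_position": float(self.start_position),
            "absorbing_threshold": float(self.absorbing_threshold),
            "temperature_kt": float(self.temperature_kt),
            "diffusion_coefficient_d0": float(self.diffusion_coefficient_d0),
            "two_sided": self.two_sided,
        }
        return self.surface.to_toml() + dumps_table("scenario", block)


def check_gradient(surface: PotentialSurface, n_points: int = 201, step: float = 1e-6,
                   rtol: float = 1e-5) -> float:
    """Max mismatch between analytic gradient and central finite difference.

    Returns the worst relative deviation (with an absolute floor of 1e-6 on
    the denominator so near-zero gradients do not blow up the ratio).
    Raises ParameterError if the mismatch exceeds ``rtol``.
    """
    lo, hi = surface.domain
    pad = (hi - lo) * 1e-3
    grid = np.linspace(lo + pad, hi - pad, n_points)
    fd = (surface.energy(grid + step) - surface.energy(grid - step)) / (2.0 * step)
    g = surface.gradient(grid)
    scale = np.maximum(np.abs(g), 1.0)
    worst = float(np.max(np.abs(g - fd) / scale))
    if worst > rtol:
        raise ParameterError(
            f"gradient of {surface.name} deviates from finite difference by {worst:.2e}"
        )
    return worst


def is_even_surface(surface: PotentialSurface, n_points: int = 101, atol: float = 1e-10) -> bool:
    """Pointwise symmetry check U(y) == U(-y) over the domain."""
    hi = min(abs(surface.domain[0]), abs(surface.domain[1]))
    grid = np.linspace(0.0, hi, n_points)
    return bool(np.allclose(surface.energy(grid), surface.energy(-grid), atol=atol))
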