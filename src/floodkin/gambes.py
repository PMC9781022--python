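"""Static Gaussian-mixture bias built from bound-state descriptor samples.

The bound-state density P(d) along the single descriptor d is estimated by
expectation--maximization on unbiased samples; the static bias is

    V(d) = kT * log( (P(d) + eps) / eps )

i.e. the mixture log-density smoothed by eps and shifted so V = 0 where
P = 0.  The smoothing parameter is tied to the energy cutoff E_cut by

    eps = P_max * exp(-E_cut / kT)

with P_max the density maximum (grid search plus local refinement), so the
bias ceiling is E_cut up to kT*log(1 + e^{-E_cut/kT}).  A vanishing bias at
vanishing density is what keeps the transition-state region unbiased, the
condition under which biased escape times can be rescaled to physical ones.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.mixture import GaussianMixture

from .errors import DataError, ParameterError

log = logging.getLogger(__name__)

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianMixtureModel:
    """1D Gaussian mixture: weights sum to 1, variances positive."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("weights must be nonnegative and sum to 1")
        if np.any(np.asarray(self.variances) <= 0):
            raise ParameterError("variances must be positive")
        if not (len(w) == len(self.means) == len(self.variances)):
            raise ParameterError("weights/means/variances lengths differ")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def pdf(self, y):
        y = np.asarray(y, dtype=float)[..., None]
        comp = np.exp(-0.5 * (y - self.means) ** 2 / self.variances) / (
            np.sqrt(self.variances) * _SQRT2PI
        )
        return np.squeeze(comp @ self.weights)

    def dpdf(self, y):
        y = np.asarray(y, dtype=float)[..., None]
        comp = np.exp(-0.5 * (y - self.means) ** 2 / self.variances) / (
            np.sqrt(self.variances) * _SQRT2PI
        )
        dcomp = comp * (-(y - self.means) / self.variances)
        return np.squeeze(dcomp @ self.weights)

    def normalization_defect(self, span_sigmas: float = 12.0, n: int = 20_001) -> float:
        """|integral of pdf - 1| by trapezoid over the mixture's support."""
        sd = np.sqrt(self.variances)
        lo = float(np.min(self.means - span_sigmas * sd))
        hi = float(np.max(self.means + span_sigmas * sd))
        grid = np.linspace(lo, hi, n)
        return abs(float(np.trapezoid(self.pdf(grid), grid)) - 1.0)


def fit_mixture(samples, n_components: int, seed: int) -> GaussianMixtureModel:
    """EM fit, best of 5 seeded restarts; deterministic for a fixed seed.

    Components whose variance collapses below 1e-12 are pruned with a
    logged warning and the weights renormalized.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    if len(samples) < 10 * n_components:
        raise DataError(
            f"need at least {10 * n_components} samples for {n_components} components, "
            f"got {len(samples)}"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        tol=1e-8,
        reg_covar=1e-12,
        max_iter=500,
        n_init=5,
        random_state=seed,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # stopping at the 500-iteration cap is an accepted outcome
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(samples[:, None])
    weights = gm.weights_.copy()
    means = gm.means_.ravel().copy()
    variances = gm.covariances_.reshape(-1).copy()
    keep = variances >= 1e-12
    if not np.all(keep):
        log.warning("pruning %d degenerate mixture component(s)", int((~keep).sum()))
        weights, means, variances = weights[keep], means[keep], variances[keep]
        weights = weights / weights.sum()
    return GaussianMixtureModel(weights=weights, means=means, variances=variances)


def em_log_likelihood_path(samples, n_components: int, seed: int, n_iter: int = 25):
    """Per-iteration EM log-likelihood (lower bound) from a warm-started fit.

    Exposed so the EM monotonicity property can be observed directly.
    """
    samples = np.asarray(samples, dtype=float).ravel()[:, None]
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        tol=0.0,
        reg_covar=1e-12,
        max_iter=1,
        n_init=1,
        warm_start=True,
        random_state=seed,
    )
    path = []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-iteration fits report non-convergence
        for _ in range(n_iter):
            gm.fit(samples)
            path.append(float(gm.lower_bound_))
    return np.asarray(path)


@dataclass(frozen=True)
class GambesBias:
    """Static mixture bias with eps tied to the energy cutoff."""

    mixture: GaussianMixtureModel
    epsilon: float
    energy_cutoff: float
    kt: float = 1.0
    #: V is already expressed in its shifted form; the equivalent additive
    #: shift relative to the raw kT*log(P + eps) form is -kT*log(eps).
    @property
    def shift(self) -> float:
        return -self.kt * math.log(self.epsilon)

    def energy(self, y):
        p = self.mixture.pdf(y)
        return self.kt * np.log1p(p / self.epsilon)

    def gradient(self, y):
        p = self.mixture.pdf(y)
        dp = self.mixture.dpdf(y)
        return self.kt * dp / (p + self.epsilon)

    # -- construction --------------------------------------------------
    @staticmethod
    def from_mixture(
        mixture: GaussianMixtureModel,
        energy_cutoff: float,
        kt: float = 1.0,
        domain: tuple[float, float] | None = None,
        n_grid: int = 2001,
    ) -> "GambesBias":
        """eps = P_max e^{-E_cut/kT}; P_max by grid search + local refinement."""
        if energy_cutoff <= 0:
            raise ParameterError("energy_cutoff must be positive")
        if domain is None:
            sd = np.sqrt(mixture.variances)
            domain = (
                float(np.min(mixture.means - 8 * sd)),
                float(np.max(mixture.means + 8 * sd)),
            )
        grid = np.linspace(domain[0], domain[1], n_grid)
        dens = np.atleast_1d(mixture.pdf(grid))
        i = int(np.argmax(dens))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        res = minimize_scalar(lambda y: -float(mixture.pdf(y)), bounds=(lo, hi), method="bounded")
        p_max = max(float(dens[i]), -float(res.fun))
        eps = p_max * math.exp(-energy_cutoff / kt)
        return GambesBias(mixture=mixture, epsilon=eps, energy_cutoff=energy_cutoff, kt=kt)

    @staticmethod
    def from_samples(
        samples,
        energy_cutoff: float,
        n_components: int = 3,
        seed: int = 0,
        kt: float = 1.0,
        domain: tuple[float, float] | None = None,
    ) -> "GambesBias":
        mixture = fit_mixture(samples, n_components, seed)
        return GambesBias.from_mixture(mixture, energy_cutoff, kt=kt, domain=domain)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.mixture.weights.tolist(),
                "means": self.mixture.means.tolist(),
                "variances": self.mixture.variances.tolist(),
                "epsilon": self.epsilon,
                "energy_cutoff": self.energy_cutoff,
                "kt": self.kt,
                "shift": self.shift,
            }
        )

    @staticmethod
    def from_json(text: str) -> "GambesBias":
        d = json.loads(text)
        mixture = GaussianMixtureModel(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
        )
        return GambesBias(
            mixture=mixture,
            epsilon=float(d["epsilon"]),
            energy_cutoff=float(d["energy_cutoff"]),
            kt=float(d.get("kt", 1.0)),
        )
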