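"""On-the-fly probability enhanced sampling, flooding variant.

The CV distribution is estimated on the fly as a weighted kernel density

    P_n(s) = sum_k w_k G(s, s_k) / sum_k w_k,      w_k = e^{V_{k-1}(s_k)/kT}

with fixed-bandwidth Gaussian kernels deposited every ``pace`` engine
steps, except inside the excluded region (which protects the transition
state: deposition is forbidden there, but the bias still exerts force
everywhere).  The bias follows the well-tempered form

    V_n(s) = (1 - 1/gamma) * kT * log( (r + eps) / eps ),
    r = min(P_n(s)/Z_n, 1),    eps = exp( -E_cut / ((1 - 1/gamma) kT) )

shifted so V = 0 where P_n = 0.  The normalization Z_n is the mean of
P_n over the deposited kernel centers, recomputed at every update.  The
density ratio is saturated at 1 so the barrier parameter E_cut is a hard
ceiling on the deposited bias (the bias force vanishes on the flat top);
this is the flooding-safety analogue of the GAMBES epsilon rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
import numpy as np

from .errors import ParameterError

_SQRT2PI = math.sqrt(2.0 * math.pi)


def excluded_outside_interval(lo: float, hi: float) -> tuple[float, float]:
    """Deposition interval [lo, hi]: everything outside is excluded."""
    if not lo < hi:
        raise ParameterError("excluded-region interval must be increasing")
    return (float(lo), float(hi))


def excluded_beyond_abs(y_excl: float) -> tuple[float, float]:
    """The |s| > y_excl convention: deposit only inside [-y_excl, y_excl]."""
    if y_excl <= 0:
        raise ParameterError("y_excl must be positive")
    return (-float(y_excl), float(y_excl))


@dataclass
class OpesBiasState:
    """Evolving kernel list + bias parameters.

    ``deposit_interval`` is the complement of the excluded region: kernels
    are only ever appended for CV values inside it.
    """

    sigma: float
    gamma: float = 10.0
    barrier: float = 7.0  # E_cut, kT units
    kt: float = 1.0
    pace: int = 500
    deposit_interval: tuple[float, float] = (-8.5, 8.5)
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    z_n: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.gamma <= 1:
            raise ParameterError("gamma must exceed 1")
        if self.barrier <= 0 or self.kt <= 0:
            raise ParameterError("barrier and kT must be positive")
        if self.pace < 1:
            raise ParameterError("pace must be >= 1")
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ParameterError("kernel weights must be positive")

    @property
    def prefactor(self) -> float:
        return (1.0 - 1.0 / self.gamma) * self.kt

    @property
    def epsilon(self) -> float:
        return math.exp(-self.barrier / self.prefactor)

    @property
    def n_kernels(self) -> int:
        return len(self.centers)

    def in_excluded_region(self, s: float) -> bool:
        lo, hi = self.deposit_interval
        return not (lo <= s <= hi)

    # -- density -------------------------------------------------------
    def probability(self, s):
        """Weighted kernel density estimate P_n(s); 0 with no kernels."""
        s = np.asarray(s, dtype=float)
        if self.n_kernels == 0:
            return np.zeros_like(s) if s.ndim else 0.0
        g = np.exp(-0.5 * ((s[..., None] - self.centers) / self.sigma) ** 2) / (
            self.sigma * _SQRT2PI
        )
        out = g @ self.weights / self.weights.sum()
        return float(out) if s.ndim == 0 else out

    def _prob_and_dprob(self, s: float) -> tuple[float, float]:
        if self.n_kernels == 0:
            return 0.0, 0.0
        d = (s - self.centers) / self.sigma
        g = np.exp(-0.5 * d * d) / (self.sigma * _SQRT2PI)
        wsum = self.weights.sum()
        p = float(g @ self.weights) / wsum
        dp = float((g * (-d / self.sigma)) @ self.weights) / wsum
        return p, dp

    # -- bias ------------------------------------------------------------
    def energy(self, s):
        s_arr = np.asarray(s, dtype=float)
        p = self.probability(s_arr)
        r = np.minimum(np.asarray(p) / self.z_n, 1.0)
        v = self.prefactor * np.log1p(r / self.epsilon)
        return float(v) if s_arr.ndim == 0 else v

    def gradient(self, s):
        s = float(s)
        p, dp = self._prob_and_dprob(s)
        r = p / self.z_n
        if r >= 1.0:  # saturated: flat bias top, zero force
            return 0.0
        return self.prefactor * (dp / self.z_n) / (r + self.epsilon)

    @property
    def max_energy_bound(self) -> float:
        """Hard upper bound on the bias: E_cut + (1-1/gamma) kT log 2."""
        return self.barrier + self.prefactor * math.log(2.0)

    # -- update ------------------------------------------------------------
    def update(self, s_now: float) -> None:
        """Deposit a kernel at ``s_now`` unless it lies in the excluded region.

        The kernel weight is e^{V_{n-1}(s_now)/kT} with the bias in force
        before this update; Z_n is then recomputed as the mean of the new
        P_n over all deposited kernel centers.
        """
        s_now = float(s_now)
        if self.in_excluded_region(s_now):
            return
        w = math.exp(self.energy(s_now) / self.kt)
        self.centers = np.append(self.centers, s_now)
        self.weights = np.append(self.weights, w)
        self.z_n = float(np.mean(self.probability(self.centers)))

    # engine hook: deposit every ``pace`` steps
    def on_step(self, y: float, step: int) -> None:
        if step % self.pace == 0:
            self.update(y)

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma": self.sigma,
                "gamma": self.gamma,
                "barrier": self.barrier,
                "kt": self.kt,
                "pace": self.pace,
                "deposit_interval": list(self.deposit_interval),
                "centers": self.centers.tolist(),
                "weights": self.weights.tolist(),
                "z_n": self.z_n,
                "epsilon": self.epsilon,
            }
        )

    @staticmethod
    def from_json(text: str) -> "OpesBiasState":
        d = json.loads(text)
        return OpesBiasState(
            sigma=float(d["sigma"]),
            gamma=float(d["gamma"]),
            barrier=float(d["barrier"]),
            kt=float(d["kt"]),
            pace=int(d["pace"]),
            deposit_interval=tuple(d["deposit_interval"]),
            centers=np.asarray(d["centers"]),
            weights=np.asarray(d["weights"]),
            z_n=float(d["z_n"]),
        )


def opes_probability(state: OpesBiasState, s):
    """Module-level alias for :meth:`OpesBiasState.probability`."""
    return state.probability(s)


def opes_bias_energy(state: OpesBiasState, s):
    """Module-level alias for :meth:`OpesBiasState.energy`."""
    return state.energy(s)


def opes_update(state: OpesBiasState, s_now: float) -> OpesBiasState:
    """Functional update: returns a new state, leaving the input unchanged."""
    new = replace(
        state,
        centers=state.centers.copy(),
        weights=state.weights.copy(),
    )
    new.update(s_now)
    return new


def bandwidth_from_bound_run(samples, factor: float = 0.5) -> float:
    """Kernel bandwidth rule: ``factor`` times the std of a short bound run."""
    sd = float(np.std(np.asarray(samples, dtype=float)))
    if sd <= 0:
        raise ParameterError("bound-state samples have zero spread")
    return factor * sd
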