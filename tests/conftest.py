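import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import floodkin as fk

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def flat_surface(half_width: float = 1000.0) -> fk.PotentialSurface:
    zero = lambda y: np.zeros_like(np.asarray(y, dtype=float))  # noqa: E731
    return fk.PotentialSurface(
        name="flat", params={}, domain=(-half_width, half_width),
        energy_fn=zero, gradient_fn=zero,
    )


def harmonic_surface(kappa: float = 4.0, half_width: float = 50.0) -> fk.PotentialSurface:
    return fk.PotentialSurface(
        name="harmonic", params={"kappa": kappa}, domain=(-half_width, half_width),
        energy_fn=lambda y: 0.5 * kappa * np.asarray(y, dtype=float) ** 2,
        gradient_fn=lambda y: kappa * np.asarray(y, dtype=float),
    )


@pytest.fixture(scope="session")
def flat():
    return flat_surface()


@pytest.fixture(scope="session")
def harmonic():
    return harmonic_surface()


@pytest.fixture(scope="session")
def double_well_4kt():
    return fk.double_well_scenario(4.0)


@pytest.fixture(scope="session")
def double_well_8kt():
    return fk.double_well_scenario(8.0)


@pytest.fixture(scope="session")
def shipped_scenarios():
    return {label: fk.build_scenario(label) for label in
            ("interlayer_center", "interlayer_mid", "interlayer_edge", "surface_desorption")}
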