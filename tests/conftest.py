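import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from demicdyn import InitialConditions, ParameterSet, Priors
from demicdyn.synthetic import identity_curve, wiggly_curve

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def priors():
    return Priors()


@pytest.fixture(scope="session")
def midpoint_theta(priors):
    mid = priors.midpoint()
    return ParameterSet(gamma_hg=mid["gamma_hg"], gamma_f=mid["gamma_f"],
                        mu=mid["mu"], delta_hg=mid["delta_hg"],
                        delta_f=mid["delta_f"], eta=mid["eta"])


@pytest.fixture(scope="session")
def prior_battery(priors):
    """Ten parameter sets + initial conditions spanning the prior supports."""
    rng = np.random.default_rng(20240901)
    draws = priors.sample(rng, 10)
    battery = []
    for _, row in draws.iterrows():
        p = ParameterSet(gamma_hg=row["gamma_hg"], gamma_f=row["gamma_f"],
                         mu=row["mu"], delta_hg=row["delta_hg"],
                         delta_f=row["delta_f"], eta=row["eta"])
        init = InitialConditions.from_rho(row["rho"], hg0=row["hg0"],
                                          k_hg=row["hg0"], k_f=1.5 * row["hg0"])
        battery.append((p, init))
    return battery


@pytest.fixture(scope="session")
def ident_curve():
    return identity_curve(5000, 9500, sigma=8.0)


@pytest.fixture(scope="session")
def sharp_curve():
    """Identity curve with near-zero curve error (closed-form checks)."""
    return identity_curve(3000, 8000, sigma=1e-3)


@pytest.fixture(scope="session")
def bumpy_curve():
    return wiggly_curve(5000, 9500, amplitude=20.0, period=500.0, sigma=8.0)
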