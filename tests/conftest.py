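import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panels():
    from ccexchange.synthetic import builtin_panels

    return builtin_panels()


@pytest.fixture(scope="session")
def ccdi(panels):
    return {p.name: p for p in panels["basis_set"]}["CC-Di"]


@pytest.fixture(scope="session")
def calibrated_intermediate():
    """Intermediate-mechanism params at the calibrated CC-Di slope."""
    from ccexchange.kinetics import intermediate_params_from_slope
    from ccexchange.synthetic import CC_DI_K_REF

    return intermediate_params_from_slope(CC_DI_K_REF, k_resolve=1000.0)


def binomial_pmf(n: int, p: float) -> np.ndarray:
    from math import comb

    return np.array([comb(n, l) * p**l * (1 - p) ** (n - l) for l in range(n + 1)])
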