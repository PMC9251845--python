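import pytest

from evotrap import ParameterSet, SimRng


@pytest.fixture
def rng() -> SimRng:
    """A fresh, fixed-seed stream for statistical unit tests."""
    return SimRng(20240917)


def scaled_params(**overrides) -> ParameterSet:
    """Desk-scale parameter set: small habitat, short horizon, fast to simulate."""
    base = dict(K1=200.0, K2=200.0, n1=8, n2=8, P0=100, generations=20,
                tau_s=3.0, scenario=1, seed=1)
    base.update(overrides)
    return ParameterSet(**base)


@pytest.fixture
def small_params() -> ParameterSet:
    return scaled_params()
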