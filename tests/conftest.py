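import numpy as np
import pytest

from vitreoflow.transport import PoroelasticParams


@pytest.fixture
def reference_params() -> PoroelasticParams:
    """The reference poroelastic parameter set: f=1, R0=1.2 cm, a=0.23 cm,
    kappa=8.4e-8 cm^4/(dyn s), P0=6.7e4 dyn/cm^2."""
    return PoroelasticParams(f=1.0, R0=1.2, a=0.23, kappa=8.4e-8, P0=6.7e4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_params(rng: np.random.Generator, n: int = 1):
    """Random valid parameter sets broadly around the reference values."""
    out = []
    for _ in range(n):
        R0 = rng.uniform(0.8, 1.6)
        out.append(PoroelasticParams(
            f=rng.uniform(0.5, 1.0),
            R0=R0,
            a=rng.uniform(0.1, 0.6) * R0,
            kappa=8.4e-8 * rng.uniform(0.2, 5.0),
            P0=6.7e4 * rng.uniform(0.2, 5.0),
        ))
    return out
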