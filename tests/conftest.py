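import numpy as np
import pytest

from ampliscope.theory import GrowthResponse, TheoryParams


@pytest.fixture
def exp_params() -> TheoryParams:
    """Canonical exponential-response parameter set used across theory tests."""
    return TheoryParams(
        mu=0.01, d=0.1, ell=0.9, lam=0.5, g=GrowthResponse("exponential", p=1.0)
    )


@pytest.fixture
def hill_params() -> TheoryParams:
    """Hill response g(A) = 1/(A^7 + 1) with moderate cost and dose scaling."""
    return TheoryParams(
        mu=0.01,
        d=0.1,
        ell=0.9,
        lam=0.5,
        g=GrowthResponse("hill", k_half=1.0, n_hill=7.0),
    )


def random_exp_params(rng: np.random.Generator) -> TheoryParams:
    """A random valid parameter draw with an exponential dose response."""
    return TheoryParams(
        mu=rng.uniform(0.0, 0.05),
        d=rng.uniform(0.0, 0.5),
        ell=rng.uniform(0.3, 0.99),
        lam=rng.uniform(0.1, 0.95),
        g=GrowthResponse("exponential", p=rng.uniform(0.2, 3.0)),
    )
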