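import numpy as np
import pytest

from purebirth import GrowthModel


@pytest.fixture(scope="session")
def grid():
    """Default dense time grid (units of 1/b), matching the production default."""
    return np.arange(0.0, 15.0001, 0.05)


@pytest.fixture(scope="session")
def coarse_grid():
    return np.arange(0.0, 15.0001, 0.25)


def four_models(K: int):
    """The four bounded growth laws at their reference exponents."""
    return {
        "logistic": GrowthModel(family="logistic", K=K),
        "blumberg": GrowthModel(family="blumberg", gamma=1.5, K=K),
        "richards": GrowthModel(family="richards", beta=2.0, K=K),
        "gompertz": GrowthModel(family="gompertz", K=K),
    }


@pytest.fixture(scope="session")
def models_k30():
    return four_models(30)


@pytest.fixture(scope="session")
def models_k100():
    return four_models(100)
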