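import numpy as np
import pytest

from splitsig import Dataset, FeatureSet
from splitsig.learners import OracleLearner, RidgeLearner
from splitsig.simulate import gen_linear_example


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def linear_data():
    """One draw of the correlated-uniform linear benchmark (N=1000)."""
    return gen_linear_example(1000, np.random.default_rng(42))


@pytest.fixture(scope="session")
def null_fs():
    """Features 4 and 5 (0-based 3, 4): irrelevant in the linear benchmark."""
    return FeatureSet((3, 4))


@pytest.fixture(scope="session")
def signal_fs():
    """Features 1-3 (0-based 0-2): the signal of the linear benchmark."""
    return FeatureSet((0, 1, 2))


@pytest.fixture(scope="session")
def ridge():
    return RidgeLearner()


@pytest.fixture(scope="session")
def linear_oracle():
    """The true regression function of the linear benchmark.

    It never reads columns 3-4, so the same function is the population
    optimum for both the full and the dual data under the null set.
    """
    return OracleLearner(lambda X: 0.02 * (X[:, 0] + X[:, 1] + X[:, 2]))


@pytest.fixture
def noise_dataset():
    """Outcome independent of all features."""

    def make(N, d=5, seed=0):
        r = np.random.default_rng(seed)
        return Dataset(r.uniform(-1, 1, (N, d)), r.standard_normal(N))

    return make
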