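import numpy as np
import pytest

from paraner.config import benchmark_config, to_model_config
from paraner.synthetic_data import MockParaphraser, SynthSpec, make_corpus


@pytest.fixture(scope="session")
def spec():
    """The fixed standard benchmark spec (seed 7)."""
    return SynthSpec()


@pytest.fixture(scope="session")
def corpus(spec):
    """(train_pool, test_set) of the standard benchmark."""
    return make_corpus(spec)


@pytest.fixture(scope="session")
def paraphraser(spec):
    return MockParaphraser(spec)


@pytest.fixture(scope="session")
def small_corpus():
    """A small corpus for fast unit tests (same generator, smaller sizes)."""
    return make_corpus(SynthSpec(n_train=40, n_test=20, seed=11))


@pytest.fixture
def model_config():
    """Desk-scale model configuration, fresh per test."""
    return to_model_config(benchmark_config())


@pytest.fixture
def rng():
    return np.random.default_rng(123)
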