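import numpy as np
import pytest

from dsrt.models import ScoreMatrix
from dsrt.simulate import benchmark_item_params


@pytest.fixture()
def rng():
    return np.random.default_rng(20201222)


@pytest.fixture()
def small_scores(rng):
    """A tiny complete 4-category score matrix (12 persons, 5 items)."""
    return ScoreMatrix(rng.integers(0, 4, size=(12, 5)))


@pytest.fixture()
def design_params_null():
    """Benchmark item parameters, null condition (no speed dimension), K=20."""
    return benchmark_item_params(20, alpha1=0.5, alpha2=0.0)


@pytest.fixture()
def design_params_speed():
    """Benchmark item parameters with unit speed slopes, K=20."""
    return benchmark_item_params(20, alpha1=0.5, alpha2=1.0)
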