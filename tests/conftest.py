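import numpy as np
import pytest

from methvar import MethylationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20151218)


@pytest.fixture
def small_matrix(rng):
    """100 null sites, 20 subjects per group, standard normal."""
    values = rng.standard_normal((100, 40))
    labels = np.repeat([0, 1], 20)
    return MethylationMatrix.from_arrays(values, labels)


@pytest.fixture
def unbalanced_matrix(rng):
    """50 null sites with unequal group sizes (12 control, 18 diseased)."""
    values = rng.standard_normal((50, 30))
    labels = np.concatenate([np.zeros(12, int), np.ones(18, int)])
    return MethylationMatrix.from_arrays(values, labels)
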