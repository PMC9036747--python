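import warnings

import numpy as np
import pytest

from leafpheno.pipeline import process_leaf
from leafpheno.synthetic import LeafParams, generate_leaf


@pytest.fixture(scope="session")
def default_leaf():
    """One deterministic, clean synthetic leaf with ground truth."""
    return generate_leaf(LeafParams(seed=1))


@pytest.fixture(scope="session")
def processed_default(default_leaf):
    """The default leaf run through the full per-leaf pipeline."""
    sample, truth = default_leaf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = process_leaf(sample)
    return result, truth


def random_masks(rng: np.random.Generator, shape=(32, 32), p=0.3):
    """A random boolean mask for set-algebra property tests."""
    return rng.random(shape) < p
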