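import numpy as np
import pytest

from gvreprog.expression import ClassificationConfig, compute_tpm
from gvreprog.synthetic import (
    ExprSimConfig,
    ImgSimConfig,
    simulate_expression,
    simulate_images,
)


@pytest.fixture(scope="session")
def default_cfg():
    return ClassificationConfig()


@pytest.fixture(scope="session")
def sim_small():
    """Default-noise simulation at reduced size for unit tests."""
    cm, truth = simulate_expression(ExprSimConfig(n_genes=1500, seed=1))
    return cm, truth


@pytest.fixture(scope="session")
def expr_small(sim_small):
    cm, truth = sim_small
    return compute_tpm(cm), truth


@pytest.fixture(scope="session")
def sim_exact():
    """Zero-noise (expected-count) simulation: truth is exactly recoverable."""
    cm, truth = simulate_expression(ExprSimConfig(n_genes=1500, seed=2, exact_counts=True))
    return cm, truth


@pytest.fixture(scope="session")
def expr_exact(sim_exact):
    cm, truth = sim_exact
    return compute_tpm(cm), truth


@pytest.fixture(scope="session")
def image_default():
    """One default two-channel image (20 nuclei incl. clusters), seed 7."""
    images, truths = simulate_images(ImgSimConfig(seed=7))
    return images[0], truths[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
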