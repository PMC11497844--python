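import numpy as np
import pytest

from popexpress.model_io import ExpressionModel, ModelVariant
from popexpress.synthetic import SyntheticConfig, make_frequencies, make_models


@pytest.fixture
def tiny_model():
    """Two genes with hand-picked weights for exact-sum checks."""
    return ExpressionModel(
        tissue="testis",
        genes={
            "gA": [
                ModelVariant("1_100_A_G_b38", "A", "G", 0.5),
                ModelVariant("1_200_C_T_b38", "C", "T", -0.2),
            ],
            "gB": [
                ModelVariant("1_300_G_A_b38", "G", "A", 1.0),
                ModelVariant("1_400_T_C_b38", "T", "C", 3.0),
            ],
        },
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(n_tissues=2, n_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_models(small_cfg):
    return make_models(small_cfg)


@pytest.fixture(scope="session")
def small_freq(small_cfg, small_models):
    return make_frequencies(small_models, small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
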