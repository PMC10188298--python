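import numpy as np
import pytest

from claps.config import RunConfig
from claps.model import CLAPSModel
from claps.smiles_data import build_vocabulary
from claps.synthetic import generate_synthetic_corpus


@pytest.fixture(scope="session")
def corpus200():
    return generate_synthetic_corpus(200, seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    """Very small model for fast unit tests (not the desk-scale run config)."""
    return RunConfig.desk_scale(d=16, projection_hidden=32, projection_out=16,
                                predictor_dims=(32, 16, 8), batch_size=8,
                                epochs_pretrain=2, epochs_finetune=5, max_len=48)


@pytest.fixture(scope="session")
def tiny_model(corpus200, tiny_config):
    vocab = build_vocabulary(corpus200)
    return CLAPSModel(vocab, tiny_config, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
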