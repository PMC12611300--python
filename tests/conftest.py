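import numpy as np
import pytest

from exprssl import DatasetSpec, EncoderConfig, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but learnable labelled dataset shared across training tests."""
    spec = DatasetSpec(n_samples=600, n_genes=40, n_classes=4,
                       n_informative_genes=20, redundancy_block_size=4,
                       redundancy_rho=0.8, class_effect_size=1.5,
                       noise_sd=1.0, seed=11)
    X, y = generate_dataset(spec)
    return spec, X, y


@pytest.fixture(scope="session")
def small_split(small_dataset):
    _, X, y = small_dataset
    return split_dataset(y, finetune_size=150, test_size=100,
                         val_fraction=0.15, seed=7)


@pytest.fixture
def tiny_encoder_config():
    return EncoderConfig(input_dim=40, n_layers=2, hidden_dim=16,
                         embedding_dim=16, seed=3)
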