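import numpy as np
import pytest

from vitfusion import (CohortConfig, ModelConfig, MultiModalViT, TrainConfig,
                       generate_cohort)
from vitfusion.training import AugmentConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def tiny_model_config():
    """32^3 volumes cut into 8^3 patches (64 tokens), narrow embeddings."""
    return ModelConfig(volume_shape=(32, 32, 32), patch3d=(8, 8, 8),
                       d_model=32, depth_3d=2, depth_2d=2, heads=4,
                       ca_heads=4, head_hidden=16)


@pytest.fixture(scope="session")
def tiny_model(tiny_model_config):
    return MultiModalViT(tiny_model_config, rng=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 subjects, 32^3 volumes, planted structural + SC-SM FNC effects."""
    config = CohortConfig(n_subjects_per_group=10, volume_shape=(32, 32, 32),
                          n_timepoints=150, seed=11)
    records, truth = generate_cohort(config)
    return config, records, truth


@pytest.fixture()
def fast_train_config():
    return TrainConfig(total_epochs=2, warmup_epochs=1, batch_size=8,
                       n_folds=5, seed=3,
                       augmentation=AugmentConfig(enabled=False))
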