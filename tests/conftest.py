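import numpy as np
import pytest

from heclip.encoders import ImageEncoderConfig
from heclip.objective import AugmentationPolicy, LossConfig
from heclip.synthetic import SyntheticConfig, generate_cohort
from heclip.training import TrainConfig, train


@pytest.fixture(scope="session")
def small_cohort():
    """A small 4-cluster cohort shared by training/retrieval tests."""
    config = SyntheticConfig(
        n_spots=120, n_genes=40, n_clusters=4, patch_size=32, n_slices=3,
        within_cluster_noise_sd=0.3, pixel_noise_sd=0.05, seed=11,
    )
    cohort, labels = generate_cohort(config)
    return cohort, labels, config


@pytest.fixture(scope="session")
def small_train_config():
    return TrainConfig(
        epochs=2, batch_size=32, learning_rate=1e-3, seed=5,
        loss=LossConfig(),
        augmentation=AugmentationPolicy(copies_per_epoch=2, seed=5),
        encoder=ImageEncoderConfig(d_o=32),
    )


@pytest.fixture(scope="session")
def small_checkpoint(small_cohort, small_train_config):
    cohort, _, _ = small_cohort
    return train(cohort, small_train_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
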