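"""Shared fixtures: tiny configs and synthetic datasets generated on the fly."""

import numpy as np
import pytest

from stackdenoise.model import ModelConfig
from stackdenoise.synth import NoiseParams, PhantomSpec, make_pair_dataset
from stackdenoise.train import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_config():
    """Smallest config that still exercises every architectural piece."""
    return ModelConfig(in_channels=1, base_channels=4, n_down_levels=2,
                       cells_per_level=1, n_heads=2)


@pytest.fixture
def tiny_train_config():
    return TrainConfig(epochs=1, steps_per_epoch=2, batch_size=1,
                       patch_shape=(2, 8, 8), learning_rate=1e-3, seed=0)


@pytest.fixture
def small_dataset(tmp_path):
    """3 tiny filament pairs on disk with a manifest (train/val/test)."""
    spec = PhantomSpec(kind="filaments", shape=(4, 24, 24), density=3,
                       psf_sigma=0.8, background=0.05)
    manifest = make_pair_dataset(
        4, spec,
        NoiseParams(10.0, 1.0, 1), NoiseParams(10.0, 1.0, 32),
        tmp_path / "ds", seed=5, split_fractions=(0.25, 0.25, 0.5),
    )
    return manifest
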