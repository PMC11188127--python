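"""Desk-scale reference experiments.

These recipes pin down the synthetic analogue of the full workflow —
backbone pretraining on one structure family, few-pair fine-tuning on a
second family, and the running-average robustness sweep — at sizes that
run in minutes on a single CPU core.  The acceptance suite and the
acceptance report script both drive the package through these entry
points so their numbers come from identical experiments.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .io import Manifest
from .model import ModelConfig
from .synth import NoiseParams, PhantomSpec, make_average_series, make_pair_dataset
from .train import Checkpoint, TrainConfig, train_backbone

#: smoke-scale model: every architectural feature, ~20k parameters
SMOKE_MODEL = ModelConfig(in_channels=1, base_channels=8, n_down_levels=2,
                          cells_per_level=1, n_heads=2)

#: photon level producing low-SNR inputs around 18 dB PSNR vs the averaged
#: high-SNR member on these phantoms
PHOTON_LEVEL = 8.0
READ_SIGMA = 1.0
HIGH_NOISE = NoiseParams(PHOTON_LEVEL, READ_SIGMA, 64)

FILAMENT_SPEC = PhantomSpec(kind="filaments", shape=(8, 64, 64), density=8,
                            psf_sigma=1.0, background=0.05)
BLOB_SPEC = PhantomSpec(kind="blobs", shape=(8, 64, 64), density=10,
                        psf_sigma=1.0, background=0.05)

BACKBONE_TRAIN = TrainConfig(epochs=8, steps_per_epoch=25, batch_size=2,
                             patch_shape=(4, 32, 32), learning_rate=3e-4,
                             lr_finetune=1e-4, seed=0)

#: 30 fine-tuning epochs, matching the published fine-tuning protocol
FINETUNE_TRAIN = TrainConfig(epochs=30, steps_per_epoch=5, batch_size=2,
                             patch_shape=(4, 32, 32), learning_rate=3e-4,
                             lr_finetune=1e-4, seed=0)

#: low-member averaging levels for the 10 fine-tune-domain pairs; the five
#: train pairs span single-shot to 16x-averaged acquisitions so the tuned
#: model stays robust across input SNR, the val/test pairs are single-shot
FINETUNE_LOW_AVERAGES = (1, 4, 8, 16, 1, 1, 1, 1, 1, 1)


def backbone_dataset(root: Path, seed: int) -> Manifest:
    """20 filament pairs: 12 train / 2 val / 6 test."""
    return make_pair_dataset(
        20, FILAMENT_SPEC, NoiseParams(PHOTON_LEVEL, READ_SIGMA, 1), HIGH_NOISE,
        Path(root) / "filaments", seed=seed, split_fractions=(0.6, 0.1, 0.3),
    )


def finetune_dataset(root: Path, seed: int) -> Manifest:
    """10 blob pairs: 5 train (mixed averaging) / 1 val / 4 test."""
    lows = [NoiseParams(PHOTON_LEVEL, READ_SIGMA, n) for n in FINETUNE_LOW_AVERAGES]
    return make_pair_dataset(
        10, BLOB_SPEC, lows, HIGH_NOISE,
        Path(root) / "blobs", seed=seed + 7700, split_fractions=(0.5, 0.1, 0.4),
    )


def train_smoke_backbone(manifest: Manifest, seed: int) -> Checkpoint:
    cfg = dataclasses.replace(BACKBONE_TRAIN, seed=seed)
    return train_backbone(manifest, SMOKE_MODEL, cfg)


def robustness_series(seed: int, n: int = 64):
    """64-repeat running-average series in the fine-tune (blob) domain."""
    return make_average_series(BLOB_SPEC, NoiseParams(PHOTON_LEVEL, READ_SIGMA, 1),
                               n=n, seed=seed + 3300)
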