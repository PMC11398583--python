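"""Shared fixtures: small scenes, labeled synthetic channels, and one
session-scoped overfit network reused by the heavier end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from wormseg import synthetic_data as sd
from wormseg.model import NetworkConfig, WormSegNet
from wormseg.training import TrainConfig, samples_from_records, train

LABELS8 = ["full", "full", "full", "full", "full", "partial", "empty", "full"]


@pytest.fixture(scope="session")
def train_scene() -> sd.SceneConfig:
    """Coarse 128 x 16 px channel scene (8 um/px) for fast network training."""
    return sd.SceneConfig.tiny(
        fov_width_px=280, fov_height_px=128, pixel_size_um=8.0,
        channel_pitch_um=128.0,
    )


@pytest.fixture(scope="session")
def tiny_scene() -> sd.SceneConfig:
    """The standard tiny preset (288 x 32 px channels at 5 um/px)."""
    return sd.SceneConfig.tiny()


@pytest.fixture(scope="session")
def labeled8(train_scene):
    """Eight ground-truthed channels (6 full / 1 partial / 1 empty)."""
    rng = np.random.default_rng(0)
    return sd.make_labeled_channels(
        train_scene, rng, LABELS8, with_fluorescence=True,
        doses=[0.0, 0.0, 1.0, 1.0, 3.0, 3.0, 9.0, 9.0],
    )


@pytest.fixture(scope="session")
def labeled8_samples(labeled8):
    return samples_from_records(labeled8)


@pytest.fixture(scope="session")
def overfit_model(labeled8_samples):
    """Tiny network overfit on the eight labeled channels (seeded).

    Shared by the overfit acceptance check, the end-to-end phenotype test
    and the CLI pipeline test; ~400 optimizer steps on the CPU.
    """
    net = WormSegNet(NetworkConfig.tiny(), seed=0)
    cfg = TrainConfig(epochs=400, batch_size=8, seed=0, lr0=1e-3,
                      rotate_deg=0.0, gamma_range=None, flip=False)
    net, history = train(net, labeled8_samples, cfg, use_augment=False)
    net._overfit_history = history
    return net
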