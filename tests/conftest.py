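"""Shared fixtures: small phantoms and separable block sets."""

from __future__ import annotations

import numpy as np
import pytest

import microflow as mf
from microflow import flow_classifier as fc


@pytest.fixture(scope="session")
def clean_generator_config() -> mf.GeneratorConfig:
    """Noise-free, drift-free desk-scale conditions (128 px, few vessels)."""
    return mf.GeneratorConfig(
        image_size=(128, 128),
        n_vessels=(3, 3),
        noise_sigma=0.0,
        shot_noise_factor=0.0,
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_generator_config):
    """A noiseless 3-vessel phantom: (stack, truth)."""
    vessels = mf.sample_vessel_tree(clean_generator_config, seed=11)
    return mf.render_video(vessels, 60, clean_generator_config, seed=12)


def make_separable_blocks(
    n: int,
    shape: tuple[int, int, int] = (16, 16, 40),
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray]:
    """Easy labeled blocks: a dark tube that either flickers or is static.

    Flowing blocks carry a travelling intensity wave inside the tube
    (temporal signal); non-flowing blocks are the static tube plus faint
    sensor noise. Classes alternate, so both are balanced. Blocks are
    unit-normalized, as the classifier expects.
    """
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    t = np.arange(shape[2])
    for i in range(n):
        flowing = i % 2 == 0
        b = np.full(shape, 0.9, dtype=np.float32)
        r0 = int(rng.integers(6, 10))
        tube = slice(r0 - 2, r0 + 2)
        b[tube, :, :] = 0.35
        if flowing:
            phase = rng.uniform(0, 2 * np.pi)
            for c in range(shape[1]):
                wave = 0.5 + 0.5 * np.sin(0.9 * c - 1.5 * t + phase)
                b[tube, c, :] *= 1 - 0.5 * wave
        b += rng.normal(0, 0.02, shape).astype(np.float32)
        blocks.append(fc.normalize_block(b))
        labels.append(int(flowing))
    return np.stack(blocks), np.asarray(labels)


@pytest.fixture(scope="session")
def separable_blocks():
    return make_separable_blocks(120)
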