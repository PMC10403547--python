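"""Shared fixtures and helpers for the segdyn test suite."""

import numpy as np
import pytest

from segdyn.stack import BinaryMask3D, VoxelStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_mask(rng, shape, p=0.3, spacing=(10.0, 1.0, 1.0)) -> BinaryMask3D:
    """Random occupancy mask with the given marginal fill probability."""
    return BinaryMask3D(rng.random(shape) < p, spacing)


def two_channel_stack(rng, shape=(4, 32, 32), timestamp=0.0) -> VoxelStack:
    """Small fluorescence-like stack with two noisy blob channels."""
    a = np.where(rng.random(shape) < 0.3, 200.0, 20.0)
    b = np.where(rng.random(shape) < 0.3, 180.0, 10.0)
    noise = rng.normal(0, 3, size=shape)
    return VoxelStack(
        channels={"A": np.clip(a + noise, 0, 255), "B": np.clip(b + noise, 0, 255)},
        spacing=(10.0, 1.0, 1.0),
        timestamp=timestamp,
    )
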