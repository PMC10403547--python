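"""Core image containers: multi-channel voxel stacks and binary masks.

Conventions used package-wide: arrays are indexed (z, y, x), 0-based, with
z index 0 the first optical section; physical voxel spacing is (dz, dy, dx)
in micrometres and may be anisotropic (a typical fluorescence z-series has
10 µm optical sections but ~1 µm pixels in-plane); time is in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelStack:
    """Multi-channel 3D intensity field with physical voxel spacing.

    Parameters
    ----------
    channels : dict mapping channel name to a 3D (z, y, x) intensity array.
    spacing : (dz, dy, dx) voxel spacing in µm, strictly positive.
    timestamp : acquisition time in hours.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VoxelStack needs at least one channel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        shapes = {c: np.asarray(a).shape for c, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError("every channel must be a 3D (z, y, x) array")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channels disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None


@dataclass
class BinaryMask3D:
    """Thresholded channel: boolean occupancy field with provenance."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    threshold_used: float = np.nan
    method: str = "fixed"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def occupied_fraction(self) -> float:
        """Fraction p of occupied voxels, the mean of the indicator field."""
        return float(self.mask.mean())
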