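"""In-memory containers for 3D multi-channel stacks and label images.

Axes are (channel, z, y, x) for intensity data and (z, y, x) for labels.
Physical positions are continuous micron coordinates; the center of voxel
``(i, j, k)`` sits at ``((i + 0.5) * dz, (j + 0.5) * dy, (k + 0.5) * dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """Multi-channel 3D intensity stack with voxel size in microns."""

    data: np.ndarray  # (channel, z, y, x)
    voxel_size: tuple[float, float, float]  # microns per (z, y, x)
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (c, z, y, x) data, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """The (z, y, x) array for one named channel."""
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not found; available: {list(self.channels)}"
            )
        return self.data[self.channels.index(name)]


@dataclass
class LabelVolume:
    """Integer-labeled (z, y, x) volume; 0 is background."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (z, y, x) labels, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.data.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic microns."""
        return float(np.prod(self.voxel_size))

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]


def positions_to_voxels(
    positions_um: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Round continuous micron positions to integer voxel indices."""
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    return np.floor(pos / np.asarray(voxel_size)).astype(int)


def voxel_centers_um(
    index: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Micron coordinates of voxel centers for integer indices."""
    return (np.asarray(index, dtype=float) + 0.5) * np.asarray(voxel_size)
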