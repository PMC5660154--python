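"""In-memory containers for single-channel volumes and multichannel stacks."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import GeometryError
from .geometry import AcquisitionGeometry


@dataclass
class VoxelStack:
    """One channel's 3-D intensity volume plus voxel metadata.

    ``intensities`` is indexed ``(z, y, x)``; ``dx, dy, dz`` are the voxel
    pitch in micrometres; ``exposure_ms`` is the camera exposure the channel
    was acquired with (used by exposure normalization).
    """

    intensities: np.ndarray
    dx: float
    dy: float
    dz: float
    channel_name: str = ""
    exposure_ms: float = 1.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise GeometryError(
                f"expected a 3-D (z, y, x) volume, got ndim={self.intensities.ndim}"
            )
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise GeometryError("voxel dimensions dx, dy, dz must all be > 0")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("stack intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    def with_intensities(self, values: np.ndarray, **changes) -> "VoxelStack":
        """Copy of this stack with new voxel data, preserving metadata."""
        return replace(self, intensities=values, **changes)

    def same_grid(self, other: "VoxelStack", rtol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            [self.dx, self.dy, self.dz], [other.dx, other.dy, other.dz], rtol=rtol
        )


@dataclass
class StackSet:
    """Registered channels of one field of view."""

    channels: dict[str, VoxelStack]
    geometry: AcquisitionGeometry | None = None

    def __getitem__(self, name: str) -> VoxelStack:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def items(self):
        return self.channels.items()


def stack_from_geometry(
    values: np.ndarray,
    geometry: AcquisitionGeometry,
    channel_name: str = "",
) -> VoxelStack:
    """Wrap an array in a :class:`VoxelStack` using ``geometry`` metadata."""
    if values.shape != geometry.shape:
        raise GeometryError(
            f"array shape {values.shape} does not match geometry shape {geometry.shape}"
        )
    return VoxelStack(
        intensities=values,
        dx=geometry.dx,
        dy=geometry.dy,
        dz=geometry.dz,
        channel_name=channel_name,
        exposure_ms=geometry.exposure_ms.get(channel_name, 1.0),
    )
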