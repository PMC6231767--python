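"""Shared containers for 3D+t microscopy volumes.

Arrays follow the scikit-image convention: axis order (z, y, x) with a
per-axis physical voxel spacing in micrometres.  Physical point coordinates
are expressed as cartesian (x, y, z) columns, so column ``2`` of a
coordinate array corresponds to array axis ``0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: default voxel spacing (z, y, x) in um for confocal stacks
DEFAULT_SPACING = (1.0, 0.24, 0.24)


@dataclass
class VolumeStack:
    """A single 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array of intensities, axis order (z, y, x).
    spacing:
        Voxel spacing in um per array axis, ``(sz, sy, sx)``.
    timestamp:
        Acquisition time in minutes relative to the onset of germband
        extension (the developmental time origin used throughout).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_size(self) -> np.ndarray:
        """Extent of the volume in um per axis (z, y, x)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) centers in um of voxels given as (n, 3) zyx indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        zyx = (idx + 0.5) * np.asarray(self.spacing)
        return zyx[:, ::-1]


def read_volume(path, spacing: tuple[float, float, float] = DEFAULT_SPACING,
                timestamp: float = 0.0) -> VolumeStack:
    """Read a 3D TIFF stack into a :class:`VolumeStack`."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return VolumeStack(data=data, spacing=spacing, timestamp=timestamp)


def write_volume(path, stack: VolumeStack) -> None:
    """Write a volume as TIFF with the z spacing recorded in ImageJ metadata."""
    sz, sy, sx = stack.spacing
    tifffile.imwrite(
        path,
        np.asarray(stack.data),
        imagej=stack.data.dtype in (np.dtype(np.float32), np.dtype(np.uint8),
                                    np.dtype(np.uint16)),
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )
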