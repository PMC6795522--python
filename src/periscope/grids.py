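"""Physical-space 3D intensity volumes and binary masks.

Conventions used throughout the package:

* arrays are indexed ``[z, y, x]``;
* ``voxel_size`` is given as ``(dx, dy, dz)`` in micrometres;
* the physical origin is the volume corner and a voxel's coordinate is its
  centre, i.e. voxel ``(iz, iy, ix)`` sits at
  ``((ix + 0.5) * dx, (iy + 0.5) * dy, (iz + 0.5) * dz)``;
* all coordinates exposed in public interfaces are physical (μm), never
  voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class VoxelGrid3D:
    """A single-channel 3D intensity volume with physical voxel sizes.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Non-negative finite intensity lattice.
    voxel_size : tuple of float
        ``(dx, dy, dz)`` in μm.
    channel_name : str
        Free-text channel identifier (e.g. ``"dna"``, ``"lamina"``).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array (z, y, x)")
        if any(s < 8 for s in self.intensities.shape):
            raise ValueError(
                f"volume too small: shape {self.intensities.shape}, need >= 8 per axis"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive lengths (dx, dy, dz)")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        """Physical spacing in array order ``(dz, dy, dx)``."""
        dx, dy, dz = self.voxel_size
        return (dz, dy, dx)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume ``(sx, sy, sz)`` in μm."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.voxel_size
        return (nx * dx, ny * dy, nz * dz)

    def physical_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Map physical ``(x, y, z)`` μm points to fractional ``(z, y, x)`` indices."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        dx, dy, dz = self.voxel_size
        idx = np.empty_like(p)
        idx[:, 0] = p[:, 2] / dz - 0.5
        idx[:, 1] = p[:, 1] / dy - 0.5
        idx[:, 2] = p[:, 0] / dx - 0.5
        return idx

    def index_to_physical(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map fractional ``(z, y, x)`` indices to physical ``(x, y, z)`` μm."""
        i = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        dx, dy, dz = self.voxel_size
        out = np.empty_like(i)
        out[:, 0] = (i[:, 2] + 0.5) * dx
        out[:, 1] = (i[:, 1] + 0.5) * dy
        out[:, 2] = (i[:, 0] + 0.5) * dz
        return out

    def contains_points(self, points_um: np.ndarray) -> np.ndarray:
        """True where physical ``(x, y, z)`` points fall inside the volume."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        sx, sy, sz = self.extent_um
        return (
            (p[:, 0] >= 0) & (p[:, 0] <= sx)
            & (p[:, 1] >= 0) & (p[:, 1] <= sy)
            & (p[:, 2] >= 0) & (p[:, 2] <= sz)
        )

    def sample(self, points_um: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the volume at physical (x, y, z) points."""
        return sample_trilinear(self.intensities, self, points_um)


@dataclass
class BinaryMask3D:
    """A boolean lattice aligned to a :class:`VoxelGrid3D`."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return float(self.mask.sum()) * dx * dy * dz


def sample_trilinear(volume: np.ndarray, grid: VoxelGrid3D, points_um: np.ndarray) -> np.ndarray:
    """Sample ``volume`` (aligned to ``grid``) at physical points by trilinear
    interpolation; coordinates clamped to the voxel-centre lattice hull."""
    idx = grid.physical_to_index(points_um).T  # (3, n) in (z, y, x)
    hi = np.array(volume.shape, dtype=float).reshape(3, 1) - 1.0
    idx = np.clip(idx, 0.0, hi)
    return ndimage.map_coordinates(np.asarray(volume, dtype=float), idx, order=1, mode="nearest")
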