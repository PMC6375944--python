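"""Cubic-voxel density volumes.

`VoxelVolume` is the common currency between the phantom generator, the
diffraction/phase-retrieval simulator and the morphometric operators.  The
grid is indexed ``[x, y, z]``; physical positions refer to voxel *centers*,
``origin_um`` is the physical coordinate (µm) of the corner of voxel
``(0, 0, 0)``.  Densities are dimensionless with 1.0 = solid calcite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SpecValidationError

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3D scalar field on a cubic-voxel grid.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Density (1.0 = solid calcite) or integer labels.
    voxel_nm : float
        Edge length of the cubic voxel, nanometres.
    origin_um : ndarray, shape (3,)
        Physical coordinate (µm) of the corner of voxel (0, 0, 0).
    """

    grid: np.ndarray
    voxel_nm: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise SpecValidationError("grid must be 3-dimensional")
        if not self.voxel_nm > 0:
            raise SpecValidationError("voxel_nm must be positive")
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        if self.origin_um.shape != (3,):
            raise SpecValidationError("origin_um must have shape (3,)")

    # ------------------------------------------------------------------
    @property
    def voxel_um(self) -> float:
        """Voxel edge in µm."""
        return self.voxel_nm / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_um ** 3

    def axis_centers_um(self, axis: int) -> np.ndarray:
        """Physical center coordinates (µm) of voxels along one axis."""
        n = self.grid.shape[axis]
        return self.origin_um[axis] + (np.arange(n) + 0.5) * self.voxel_um

    def center_um(self) -> np.ndarray:
        """Physical coordinate of the geometric center of the grid."""
        return self.origin_um + np.asarray(self.grid.shape) * self.voxel_um / 2.0

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.grid.copy(), self.voxel_nm, self.origin_um.copy())

    def with_grid(self, grid: np.ndarray) -> "VoxelVolume":
        """Same geometry, new grid (shapes must match)."""
        if grid.shape != self.grid.shape:
            raise SpecValidationError("replacement grid must have the same shape")
        return VoxelVolume(grid, self.voxel_nm, self.origin_um.copy())
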