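"""Cartesian attenuation volumes.

The world coordinate frame is centred on the volume: a voxel with index
``(iz, iy, ix)`` has its centre at ``((i + 0.5) * spacing - n * spacing / 2)``
on each axis, in micrometres.  ``z`` is the vial's nominal vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CartesianVolume:
    """A reconstructed 3D attenuation field with isotropic voxel spacing.

    Parameters
    ----------
    data:
        Scalar attenuation values, indexed ``(z, y, x)``.
    spacing:
        Isotropic voxel edge length in micrometres.
    timestamp:
        Acquisition time attributed to this volume, in seconds (normally
        the midpoint of its reconstruction window).
    """

    data: np.ndarray
    spacing: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not self.spacing > 0:
            raise ValueError(f"voxel spacing must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (um) of voxel centres along ``axis`` (0=z,1=y,2=x)."""
        n = self.data.shape[axis]
        return (np.arange(n) + 0.5) * self.spacing - n * self.spacing / 2.0

    def extent(self, axis: int) -> tuple[float, float]:
        """World extent (um) covered by the volume along ``axis``."""
        n = self.data.shape[axis]
        half = n * self.spacing / 2.0
        return (-half, half)

    def index_from_world(self, coords_um: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) in ``(x, y, z)`` um to fractional
        ``(z, y, x)`` voxel indices."""
        coords_um = np.asarray(coords_um, dtype=float)
        nz, ny, nx = self.data.shape
        out = np.empty(coords_um.shape, dtype=float)
        for k, n in zip(range(3), (nz, ny, nx)):
            # world axis order is x,y,z; index order z,y,x
            out[..., k] = (coords_um[..., 2 - k] + n * self.spacing / 2.0) / self.spacing - 0.5
        return out
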