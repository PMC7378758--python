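"""Scan geometry arithmetic and the aligned cylindrical grid.

A gantry-based cone-beam scanner magnifies the object by SDD/SOD and scans
continuously; a sliding window over the rotations yields a time series of
reconstructed volumes, each attributed to the midpoint of its window.

The analysis grid follows the vial's symmetry axis: wedge voxels indexed
``(h, phi, r)`` with constant radial and height spacing and the number of
azimuthal divisions chosen so a wedge's azimuthal arc at the outer sample
radius equals its radial size.  Cartesian reconstructions are resampled
onto that grid by spline interpolation along the fitted axis.  (A
reconstructor working natively on the cylindrical grid would avoid the
interpolation entirely; this package deliberately consumes
already-reconstructed Cartesian volumes and documents the residual
interpolation error in its tests.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pose import VialPose
from .volume import CartesianVolume

__all__ = [
    "ConeBeamGeometry",
    "AcquisitionSchedule",
    "CylindricalGridSpec",
    "CylindricalVolume",
    "magnification_and_voxel",
    "reconstruction_schedule",
    "azimuthal_divisions",
    "resample_to_cylindrical",
    "axis_basis",
]


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Source-detector geometry of a cone-beam scanner."""

    sdd_mm: float  # source-to-detector distance
    sod_mm: float  # source-to-object distance
    pixel_pitch_um: float  # detector pixel pitch

    def __post_init__(self) -> None:
        if not (0 < self.sod_mm < self.sdd_mm):
            raise ValueError(f"need 0 < SOD < SDD, got SOD={self.sod_mm}, SDD={self.sdd_mm}")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel pitch must be > 0")


def magnification_and_voxel(geom: ConeBeamGeometry) -> tuple[float, float]:
    """Geometric magnification SDD/SOD and the projected pixel size (um)."""
    mag = geom.sdd_mm / geom.sod_mm
    return mag, geom.pixel_pitch_um / mag


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Sliding-window reconstruction schedule over a continuous scan.

    ``window`` and ``step`` are in units of full rotations; each entry of
    ``times_s`` is ``(start, mid, end)`` with mid the attributed timestamp.
    """

    rotation_time_s: float
    projections_per_rotation: int
    n_rotations: int
    window: float
    step: float
    times_s: tuple[tuple[float, float, float], ...]

    @property
    def n_volumes(self) -> int:
        return len(self.times_s)

    @property
    def interval_s(self) -> float:
        """Time between consecutive volume midpoints."""
        return self.step * self.rotation_time_s

    @property
    def total_span_s(self) -> float:
        """End of the last reconstruction window."""
        return self.times_s[-1][2]

    @property
    def mid_timestamps_s(self) -> np.ndarray:
        return np.array([t[1] for t in self.times_s])


def reconstruction_schedule(
    n_rotations: int,
    rotation_time_s: float,
    window: float = 1.0,
    step: float = 1.0,
    projections_per_rotation: int = 1600,
) -> AcquisitionSchedule:
    """Build the sliding-window schedule for a continuous-rotation scan.

    The number of volumes is ``floor((n_rotations - window) / step) + 1``;
    volume ``i`` covers rotations ``[i * step, i * step + window]``.
    """
    if not 0 < step <= window:
        raise ValueError("need 0 < step <= window")
    if window > n_rotations:
        raise ValueError(f"window of {window} rotations exceeds the scan's {n_rotations}")
    # 1e-9 guards against float representation of e.g. step = 0.1
    n_vol = int(math.floor((n_rotations - window) / step + 1e-9)) + 1
    times = []
    for i in range(n_vol):
        start = i * step * rotation_time_s
        end = i * step * rotation_time_s + window * rotation_time_s
        times.append((start, (start + end) / 2.0, end))
    return AcquisitionSchedule(
        rotation_time_s=rotation_time_s,
        projections_per_rotation=projections_per_rotation,
        n_rotations=n_rotations,
        window=window,
        step=step,
        times_s=tuple(times),
    )


def azimuthal_divisions(outer_radius_um: float, dr_um: float) -> int:
    """Azimuthal division count making the wedge arc at the outer radius
    equal to the radial voxel size: ``round(2 pi R / dr)``."""
    if outer_radius_um < dr_um:
        raise ValueError("outer radius must be at least one radial voxel")
    return int(np.round(2.0 * np.pi * outer_radius_um / dr_um))


@dataclass(frozen=True)
class CylindricalGridSpec:
    """Aligned cylindrical wedge-voxel grid.

    Voxel centres: ``r_k = (k + 0.5) dr``, ``phi_j = (j + 0.5) * 2pi/n_phi``
    (right-handed about the axis, phi = 0 toward world +x projected off the
    axis), ``h_i = h0 + i * dh`` measured along the axis from ``origin`` (a
    world (x, y, z) um point on the axis).
    """

    dr_um: float
    dh_um: float
    n_r: int
    n_phi: int
    n_h: int
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    h0_um: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dr_um > 0 and self.dh_um > 0):
            raise ValueError("grid spacings must be > 0")
        if self.n_phi < 3:
            raise ValueError("need at least 3 azimuthal divisions")
        if self.n_r < 1 or self.n_h < 1:
            raise ValueError("grid must have at least one radial and one height voxel")

    @property
    def outer_radius_um(self) -> float:
        return self.n_r * self.dr_um

    @property
    def r_centers_um(self) -> np.ndarray:
        return (np.arange(self.n_r) + 0.5) * self.dr_um

    @property
    def phi_centers_rad(self) -> np.ndarray:
        return (np.arange(self.n_phi) + 0.5) * (2 * np.pi / self.n_phi)

    @property
    def h_centers_um(self) -> np.ndarray:
        return self.h0_um + np.arange(self.n_h) * self.dh_um

    @classmethod
    def for_volume(
        cls,
        volume: CartesianVolume,
        pose: VialPose,
        outer_radius_um: float,
        dr_um: float = 30.0,
        dh_um: float = 30.0,
    ) -> "CylindricalGridSpec":
        """Grid covering the volume's height span around the fitted axis,
        with the azimuthal count set by the wedge-size rule."""
        n_r = int(math.ceil(outer_radius_um / dr_um))
        lo, hi = volume.extent(0)
        n_h = int(math.floor((hi - lo) / dh_um))
        origin = pose.axis_xy_at_z(lo)
        return cls(
            dr_um=dr_um,
            dh_um=dh_um,
            n_r=n_r,
            n_phi=azimuthal_divisions(n_r * dr_um, dr_um),
            n_h=n_h,
            origin_um=(float(origin[0]), float(origin[1]), lo),
            h0_um=0.5 * dh_um,
        )


@dataclass
class CylindricalVolume:
    """Scalar field on the aligned cylindrical grid, indexed (h, phi, r).

    The phi axis is periodic.  ``valid`` is False where resampling left the
    source volume's extent; those voxels hold ``fill_value``.
    """

    data: np.ndarray
    spec: CylindricalGridSpec
    timestamp: float = 0.0
    valid: np.ndarray | None = None
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        expected = (self.spec.n_h, self.spec.n_phi, self.spec.n_r)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} does not match grid {expected}")
        if self.valid is None:
            self.valid = np.ones(expected, dtype=bool)


def axis_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal basis (e1, e2) perpendicular to the axis with
    e1 along world +x projected off the axis and e2 = d x e1 (right-handed
    azimuth)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    e1 = np.array([1.0, 0.0, 0.0]) - d[0] * d
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise ValueError("axis parallel to world +x; azimuth basis undefined")
    e1 = e1 / n1
    return e1, np.cross(d, e1)


def resample_to_cylindrical(
    volume: CartesianVolume,
    pose: VialPose,
    spec: CylindricalGridSpec,
    order: int = 3,
    fill_value: float = 0.0,
) -> CylindricalVolume:
    """Sample the Cartesian volume at the wedge-voxel centres of ``spec``.

    Spline interpolation of the given ``order``; sample points outside the
    Cartesian extent are set to ``fill_value`` and flagged invalid rather
    than clamped, so volume edges cannot leak into downstream maps.
    """
    d = pose.direction / np.linalg.norm(pose.direction)
    e1, e2 = axis_basis(d)
    origin = np.asarray(spec.origin_um, dtype=float)
    # the declared origin must sit inside the lateral field of view
    for ax, val in ((2, origin[0]), (1, origin[1])):
        lo, hi = volume.extent(ax)
        if not (lo <= val <= hi):
            raise ValueError("axis origin lies outside the volume extent")

    h = spec.h_centers_um[:, None, None]
    phi = spec.phi_centers_rad[None, :, None]
    r = spec.r_centers_um[None, None, :]
    radial = np.cos(phi)[..., None] * e1 + np.sin(phi)[..., None] * e2
    world = origin + h[..., None] * d + r[..., None] * radial
    idx = volume.index_from_world(world)  # (..., 3) as (z, y, x)
    nz, ny, nx = volume.shape
    inside = (
        (idx[..., 0] >= 0) & (idx[..., 0] <= nz - 1)
        & (idx[..., 1] >= 0) & (idx[..., 1] <= ny - 1)
        & (idx[..., 2] >= 0) & (idx[..., 2] <= nx - 1)
    )
    coords = np.moveaxis(idx, -1, 0)
    data = ndimage.map_coordinates(
        volume.data.astype(float), coords, order=order, mode="constant", cval=fill_value
    )
    data[~inside] = fill_value
    return CylindricalVolume(
        data=data, spec=spec, timestamp=volume.timestamp, valid=inside, fill_value=fill_value
    )
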