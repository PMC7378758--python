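"""Synthetic 4D phantom of a spin-frozen vial during primary drying.

A spin-frozen vial holds its product as a thin annular layer frozen onto the
inner glass wall.  During primary drying the ice sublimates at its inner
(vacuum-facing) surface, so the frozen annulus keeps a fixed outer radius
while its inner radius recedes outward, leaving a low-density dry cake
behind.  The phantom renders that geometry as concentric regions around a
configurable, possibly misaligned, vial axis:

    vacuum core | dry cake layer | ice annulus | glass wall | heating wrap

and evolves the local ice thickness ``L(h, phi, t) = max(0, L0 - rho * t)``
from per-location initial-thickness and sublimation-rate fields.  Cracks
(rectangular notches eating into the inner ice surface) and cavities
(ellipsoidal voids buried in the ice) can be added, plus Gaussian noise.
Every generated sequence comes with its full ground truth so downstream
stages (pose estimation, segmentation, thickness maps, kinetics) can be
tested against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume import CartesianVolume

__all__ = [
    "Crack",
    "Cavity",
    "RegionAttenuation",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "add_noise",
    "default_segmentation_windows",
]


@dataclass(frozen=True)
class Crack:
    """Rectangular notch in (h, phi) removing ice from the inner surface.

    ``h_center`` is measured along the vial axis from the volume centre (um);
    ``phi_center``/``phi_width`` are radians; ``depth`` is the radial amount
    of ice removed (um).
    """

    h_center: float
    h_width: float
    phi_center: float
    phi_width: float
    depth: float


@dataclass(frozen=True)
class Cavity:
    """Ellipsoidal void inside the ice annulus.

    Semi-axes are given along height (um), azimuthal arc length at the
    cavity's radius (um) and radius (um).
    """

    h_center: float
    phi_center: float
    r_center: float
    h_semi: float
    arc_semi: float
    r_semi: float

    def intersects_ray(self, h: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Whether the radial ray at (h, phi) passes through the cavity."""
        h = np.asarray(h, dtype=float)
        dphi = _wrap_angle(np.asarray(phi, dtype=float) - self.phi_center)
        arc = dphi * self.r_center
        return (h - self.h_center) ** 2 / self.h_semi**2 + arc**2 / self.arc_semi**2 <= 1.0


@dataclass(frozen=True)
class RegionAttenuation:
    """Mean attenuation per region, arbitrary units.

    Defaults keep the dry cake barely above vacuum (the layer is nearly
    invisible in real scans) and order ice above the heating wrap; glass is
    the densest material present.  These are free parameters of the phantom,
    not calibrated to any instrument.
    """

    vacuum: float = 0.0
    dry: float = 6.0
    ice: float = 100.0
    glass: float = 220.0
    wrap: float = 60.0
    background: float = 0.0


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi


def _as_field(value, name: str) -> np.ndarray:
    """Coerce a scalar or 2D (n_h, n_phi) array to a 2D field array."""
    arr = np.atleast_2d(np.asarray(value, dtype=float))
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a scalar or 2D (n_h, n_phi) array")
    return arr


@dataclass
class PhantomConfig:
    """Full description of a synthetic vial scan.

    ``l0_um`` and ``rate_um_per_h`` may be scalars or 2D ``(n_h, n_phi)``
    fields; a field spans the volume height and the full azimuth and is
    interpolated bilinearly (periodic in phi, clamped in h).
    """

    shape: tuple[int, int, int] = (64, 64, 64)  # (nz, ny, nx)
    spacing_um: float = 30.0
    axis_offset_um: tuple[float, float] = (0.0, 0.0)  # (x, y) at mid-height
    tilt_deg: float = 0.0
    tilt_azimuth_deg: float = 0.0
    r_core_um: float = 300.0
    r_ice_outer_um: float = 750.0
    r_glass_outer_um: float = 840.0
    r_wrap_outer_um: float = 900.0
    attenuation: RegionAttenuation = field(default_factory=RegionAttenuation)
    l0_um: object = 420.0
    rate_um_per_h: object = 0.0
    cracks: tuple[Crack, ...] = ()
    cavities: tuple[Cavity, ...] = ()
    noise_sigma: float = 0.0
    timestamps_s: tuple[float, ...] = (0.0,)
    seed: int = 0
    supersample: int = 2

    def __post_init__(self) -> None:
        radii = (self.r_core_um, self.r_ice_outer_um, self.r_glass_outer_um, self.r_wrap_outer_um)
        if not all(b > a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
            raise ValueError(f"region radii must be positive and strictly increasing, got {radii}")
        if not self.spacing_um > 0:
            raise ValueError("voxel spacing must be > 0")
        ts = np.asarray(self.timestamps_s, dtype=float)
        if ts.size < 1 or np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be non-empty and strictly increasing")
        self.l0_um = _as_field(self.l0_um, "l0_um")
        self.rate_um_per_h = _as_field(self.rate_um_per_h, "rate_um_per_h")
        if np.any(self.rate_um_per_h < 0):
            raise ValueError("sublimation rate field must be >= 0")
        if np.any(self.l0_um < 0):
            raise ValueError("initial thickness field must be >= 0")
        room = self.r_ice_outer_um - self.r_core_um
        if np.any(self.l0_um > room + 1e-9):
            raise ValueError(
                f"initial ice thickness up to {self.l0_um.max():g} um exceeds the "
                f"annulus room r_ice_outer - r_core = {room:g} um"
            )
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    # -- derived geometry ---------------------------------------------------

    @property
    def axis_direction(self) -> np.ndarray:
        """Unit axis direction (x, y, z), tilted from +z."""
        t = math.radians(self.tilt_deg)
        a = math.radians(self.tilt_azimuth_deg)
        return np.array([math.sin(t) * math.cos(a), math.sin(t) * math.sin(a), math.cos(t)])

    @property
    def axis_point(self) -> np.ndarray:
        """A point on the axis (x, y, z um): the configured offset at z = 0."""
        return np.array([self.axis_offset_um[0], self.axis_offset_um[1], 0.0])

    def field_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(h, phi) sample coordinates of the thickness/rate fields."""
        n_h, n_phi = self.l0_um.shape
        nz = self.shape[0]
        half_h = nz * self.spacing_um / 2.0
        if n_h == 1:
            h = np.array([0.0])
        else:
            h = np.linspace(-half_h, half_h, n_h)
        phi = np.arange(n_phi) * (2 * np.pi / n_phi)
        return h, phi


def _eval_field(field_arr: np.ndarray, h_nodes: np.ndarray, h: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Bilinear evaluation of an (n_h, n_phi) field: clamped in h, periodic in phi."""
    n_h, n_phi = field_arr.shape
    if n_h == 1 and n_phi == 1:
        return np.full(np.broadcast(h, phi).shape, float(field_arr[0, 0]), dtype=float)
    # fractional indices
    if n_h == 1:
        ih = np.zeros_like(np.asarray(h, dtype=float))
    else:
        ih = np.interp(h, h_nodes, np.arange(n_h, dtype=float))
    ip = np.mod(np.asarray(phi, dtype=float), 2 * np.pi) / (2 * np.pi / n_phi)
    i0 = np.clip(np.floor(ih).astype(np.int64), 0, n_h - 1)
    i1 = np.minimum(i0 + 1, n_h - 1)
    fh = ih - i0
    j0 = np.floor(ip).astype(np.int64) % n_phi
    j1 = (j0 + 1) % n_phi
    fp = ip - np.floor(ip)
    return (
        field_arr[i0, j0] * (1 - fh) * (1 - fp)
        + field_arr[i0, j1] * (1 - fh) * fp
        + field_arr[i1, j0] * fh * (1 - fp)
        + field_arr[i1, j1] * fh * fp
    )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom sequence."""

    config: PhantomConfig

    @property
    def axis_point(self) -> np.ndarray:
        return self.config.axis_point

    @property
    def axis_direction(self) -> np.ndarray:
        return self.config.axis_direction

    def axis_xy_at_z(self, z_um) -> np.ndarray:
        """Axis intersection (x, y) with the horizontal plane at height z."""
        p, d = self.axis_point, self.axis_direction
        s = (np.asarray(z_um, dtype=float) - p[2]) / d[2]
        return np.stack([p[0] + s * d[0], p[1] + s * d[1]], axis=-1)

    def thickness_at(self, t_s: float, h: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """True ice thickness L(h, phi, t) in um, including cracks."""
        cfg = self.config
        h_nodes, _ = cfg.field_coords()
        h = np.asarray(h, dtype=float)
        phi = np.asarray(phi, dtype=float)
        l0 = _eval_field(cfg.l0_um, h_nodes, h, phi)
        rho = _eval_field(cfg.rate_um_per_h, h_nodes, h, phi)
        thick = np.clip(l0 - rho * (t_s / 3600.0), 0.0, None)
        for crack in cfg.cracks:
            inside = (np.abs(h - crack.h_center) <= crack.h_width / 2.0) & (
                np.abs(_wrap_angle(phi - crack.phi_center)) <= crack.phi_width / 2.0
            )
            thick = np.where(inside, np.clip(thick - crack.depth, 0.0, None), thick)
        return thick

    def rate_at(self, h: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """True local sublimation rate (um/h) at (h, phi)."""
        cfg = self.config
        h_nodes, _ = cfg.field_coords()
        return _eval_field(cfg.rate_um_per_h, h_nodes, h, phi)

    def sublimation_time_s(self, h: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Time (s) when the base linear decline reaches zero; inf if never."""
        cfg = self.config
        h_nodes, _ = cfg.field_coords()
        l0 = _eval_field(cfg.l0_um, h_nodes, h, phi)
        rho = _eval_field(cfg.rate_um_per_h, h_nodes, h, phi)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(rho > 0, l0 / rho * 3600.0, np.inf)
        return np.where(l0 <= 0, 0.0, t)

    def grid_coords(self, spec) -> tuple[np.ndarray, np.ndarray]:
        """(h, phi) truth coordinates of every location of a cylindrical
        grid spec aligned with the true axis.

        ``h`` is measured along the axis from the volume-centre axis point
        (the frame the truth fields live in); ``phi`` matches the grid's
        azimuth convention because both use the +x-projection basis.
        """
        off = float((np.asarray(spec.origin_um) - self.axis_point) @ self.axis_direction)
        h = off + spec.h_centers_um
        shape = (spec.n_h, spec.n_phi)
        return (
            np.broadcast_to(h[:, None], shape),
            np.broadcast_to(spec.phi_centers_rad[None, :], shape),
        )

    def cavity_ray_mask(self, h: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """True where a radial ray at (h, phi) intersects any configured cavity."""
        h = np.asarray(h, dtype=float)
        phi = np.asarray(phi, dtype=float)
        mask = np.zeros(np.broadcast(h, phi).shape, dtype=bool)
        for cav in self.config.cavities:
            mask |= cav.intersects_ray(h, phi)
        return mask


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (e1, e2): e1 is world +x projected off the
    axis, e2 = d x e1, so phi is right-handed about the axis with phi=0
    toward +x."""
    d = direction / np.linalg.norm(direction)
    e1 = np.array([1.0, 0.0, 0.0]) - d[0] * d
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise ValueError("axis direction parallel to +x; cannot build azimuth basis")
    e1 = e1 / n1
    e2 = np.cross(d, e1)
    return e1, e2


def generate_phantom(config: PhantomConfig) -> tuple[list[CartesianVolume], PhantomTruth]:
    """Render one volume per timestamp plus the matching ground truth.

    Voxel values are partial-volume means over a ``supersample``^3 subgrid
    of region attenuations, so material boundaries fall smoothly across
    voxels as in real CT reconstructions.
    """
    cfg = config
    nz, ny, nx = cfg.shape
    ss = cfg.supersample
    sp = cfg.spacing_um
    att = cfg.attenuation

    # Fine-grid world coordinates (volume-centred), float32 to bound memory.
    def fine(n: int) -> np.ndarray:
        return ((np.arange(n * ss, dtype=np.float32) + 0.5) / ss) * sp - n * sp / 2.0

    zf = fine(nz)[:, None, None]
    yf = fine(ny)[None, :, None]
    xf = fine(nx)[None, None, :]

    p0 = cfg.axis_point.astype(np.float32)
    d = cfg.axis_direction.astype(np.float32)
    e1, e2 = _axis_frame(cfg.axis_direction)
    e1 = e1.astype(np.float32)
    e2 = e2.astype(np.float32)

    # Axis-relative cylindrical coordinates at every fine sample.
    vx, vy, vz = xf - p0[0], yf - p0[1], zf - p0[2]
    h = vx * d[0] + vy * d[1] + vz * d[2]
    a1 = vx * e1[0] + vy * e1[1] + vz * e1[2]
    a2 = vx * e2[0] + vy * e2[1] + vz * e2[2]
    r = np.sqrt(a1 * a1 + a2 * a2)
    phi = np.mod(np.arctan2(a2, a1), np.float32(2 * np.pi))
    del vx, vy, vz, a1, a2

    truth = PhantomTruth(config=cfg)
    rng_root = np.random.SeedSequence(cfg.seed)
    frame_seeds = rng_root.spawn(len(cfg.timestamps_s))

    volumes: list[CartesianVolume] = []
    for t_s, fseed in zip(cfg.timestamps_s, frame_seeds):
        thick = truth.thickness_at(t_s, h, phi).astype(np.float32)
        r_inner = np.float32(cfg.r_ice_outer_um) - thick
        vals = np.where(
            r < cfg.r_core_um,
            np.float32(att.vacuum),
            np.where(
                r < r_inner,
                np.float32(att.dry),
                np.where(
                    r < cfg.r_ice_outer_um,
                    np.float32(att.ice),
                    np.where(
                        r < cfg.r_glass_outer_um,
                        np.float32(att.glass),
                        np.where(r < cfg.r_wrap_outer_um, np.float32(att.wrap), np.float32(att.background)),
                    ),
                ),
            ),
        )
        del thick, r_inner
        for cav in cfg.cavities:
            dphi = _wrap_angle(phi - cav.phi_center)
            inside = (
                (h - cav.h_center) ** 2 / cav.h_semi**2
                + (dphi * cav.r_center) ** 2 / cav.arc_semi**2
                + (r - cav.r_center) ** 2 / cav.r_semi**2
            ) <= 1.0
            vals = np.where(inside, np.float32(att.vacuum), vals)
        # partial-volume average over ss^3 blocks
        data = vals.reshape(nz, ss, ny, ss, nx, ss).mean(axis=(1, 3, 5), dtype=np.float32)
        del vals
        if cfg.noise_sigma > 0:
            rng = np.random.default_rng(fseed)
            data = data + rng.normal(0.0, cfg.noise_sigma, size=data.shape).astype(np.float32)
        volumes.append(CartesianVolume(data=data, spacing=sp, timestamp=float(t_s)))
    return volumes, truth


def add_noise(volume: CartesianVolume, sigma: float, seed: int) -> CartesianVolume:
    """Additive zero-mean Gaussian noise, reproducible under ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return CartesianVolume(volume.data.copy(), volume.spacing, volume.timestamp)
    rng = np.random.default_rng(seed)
    noisy = volume.data + rng.normal(0.0, sigma, size=volume.data.shape).astype(volume.data.dtype, copy=False)
    return CartesianVolume(noisy, volume.spacing, volume.timestamp)


def default_segmentation_windows(
    config: PhantomConfig,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Hard and soft grey windows for the ice phase of a phantom.

    Half-widths are 3 and 5 noise standard deviations, floored at 25% /
    40% of the smallest contrast between ice and its neighbouring regions
    so the windows stay meaningful on noise-free phantoms.  Real scans
    need instrument-specific windows.
    """
    att = config.attenuation
    gap = min(abs(att.ice - att.dry), abs(att.ice - att.glass), abs(att.ice - att.vacuum))
    hard_hw = max(3.0 * config.noise_sigma, 0.25 * gap)
    soft_hw = max(5.0 * config.noise_sigma, 0.40 * gap)
    soft_hw = min(soft_hw, 0.49 * gap)  # never let the soft window reach a neighbour mean
    hard_hw = min(hard_hw, soft_hw)
    return (att.ice - hard_hw, att.ice + hard_hw), (att.ice - soft_hw, att.ice + soft_hw)
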