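"""Frozen-layer segmentation on the cylindrical grid.

The chain mirrors the analysis of a drying spin-frozen vial: an
edge-preserving bilateral filter suppresses reconstruction noise, a dual
(hysteresis) threshold isolates the homogeneous ice phase, a 3D majority
median filter removes residual speckle, and per-(h, phi) radial edges of
the labelled layer are extracted.  A 3x3x3 Sobel-Feldman gradient gives
the angle of the local surface normal to the radial axis.  All operations
treat the phi axis as periodic (wedge voxels across phi = 0 are physically
adjacent) and replicate at the r and h boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentedLayer",
    "AngleField",
    "bilateral_filter",
    "dual_threshold",
    "median_filter_3d",
    "extract_layer_edges",
    "surface_normal_angles",
    "build_exclusion_mask",
]

EMPTY = -1  # sentinel r-index for rays with no ice


@dataclass
class SegmentedLayer:
    """Binary ice labels plus per-(h, phi) radial edge indices.

    ``first``/``last`` are the innermost and outermost ice r-indices along
    each radial ray (:data:`EMPTY` where the ray holds no ice or is
    excluded); ``count`` is the number of ice voxels on the ray.
    """

    labels: np.ndarray  # (n_h, n_phi, n_r) bool
    first: np.ndarray  # (n_h, n_phi) int
    last: np.ndarray
    count: np.ndarray
    exclusion: np.ndarray  # (n_h, n_phi) bool, True = excluded


@dataclass
class AngleField:
    """Per-voxel angle (degrees, [0, 90]) between the local surface normal
    and the radial axis; ``valid`` is False where the gradient magnitude is
    below the floor (no surface)."""

    angle_deg: np.ndarray
    valid: np.ndarray


def _pad(data: np.ndarray, radius: tuple[int, int, int]) -> np.ndarray:
    """Pad an (h, phi, r) array: replicate in h and r, wrap in phi."""
    rh, rp, rr = radius
    out = np.pad(data, ((rh, rh), (0, 0), (rr, rr)), mode="edge")
    return np.pad(out, ((0, 0), (rp, rp), (0, 0)), mode="wrap")


def _data_of(vol) -> np.ndarray:
    return vol.data if hasattr(vol, "spec") else np.asarray(vol)


def _like(vol, data: np.ndarray):
    if hasattr(vol, "spec"):
        from .geometry import CylindricalVolume

        return CylindricalVolume(
            data=data, spec=vol.spec, timestamp=vol.timestamp,
            valid=None if vol.valid is None else vol.valid.copy(),
            fill_value=vol.fill_value,
        )
    return data


def bilateral_filter(vol, sigma_spatial: float, sigma_range: float, truncate: float = 3.0):
    """Edge-preserving bilateral smoothing of an (h, phi, r) field.

    Spatial weights are a sampled Gaussian of ``sigma_spatial`` voxels
    truncated at ``truncate`` sigmas; range weights are a Gaussian of
    ``sigma_range`` in attenuation units on the centre-neighbour value
    difference.  With ``sigma_range = inf`` the filter reduces exactly to
    the corresponding Gaussian smoothing.  Accepts a CylindricalVolume or
    a bare array and returns the same kind.
    """
    if not (sigma_spatial > 0 and sigma_range > 0):
        raise ValueError("bilateral sigmas must be > 0")
    data = _data_of(vol)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(float)
    radius = int(truncate * sigma_spatial + 0.5)
    offs = np.arange(-radius, radius + 1)
    g1 = np.exp(-0.5 * (offs / sigma_spatial) ** 2)
    padded = _pad(data, (radius, radius, radius))
    num = np.zeros_like(data)
    den = np.zeros_like(data)
    n0, n1, n2 = data.shape
    inf_range = np.isinf(sigma_range)
    for a, wa in zip(offs, g1):
        for b, wb in zip(offs, g1):
            for c, wc in zip(offs, g1):
                shifted = padded[
                    radius + a : radius + a + n0,
                    radius + b : radius + b + n1,
                    radius + c : radius + c + n2,
                ]
                w = float(wa * wb * wc)  # python float keeps float32 inputs float32
                if inf_range:
                    wmat = w
                else:
                    wmat = w * np.exp(-0.5 * ((shifted - data) / sigma_range) ** 2)
                num += wmat * shifted
                den += wmat
    return _like(vol, num / den)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def dual_threshold(
    vol,
    hard_window: tuple[float, float],
    soft_window: tuple[float, float],
) -> np.ndarray:
    """Hysteresis segmentation of the ice phase.

    Voxels inside the hard grey window are ice; voxels inside the soft
    window become ice iff they are 26-connected (with azimuthal wrap) to a
    hard voxel.  The soft window must contain the hard window.  Returns a
    boolean label array.
    """
    (hlo, hhi), (slo, shi) = hard_window, soft_window
    if not (hlo < hhi and slo < shi):
        raise ValueError("windows must satisfy lo < hi")
    if not (slo <= hlo and shi >= hhi):
        raise ValueError("soft window must contain the hard window")
    data = _data_of(vol)
    hard = (data >= hlo) & (data <= hhi)
    soft = (data >= slo) & (data <= shi)
    if not hard.any():
        warnings.warn("empty hard window: segmentation is empty", stacklevel=2)
        return np.zeros_like(hard)
    structure = np.ones((3, 3, 3), dtype=bool)
    lab, nlab = ndimage.label(soft, structure=structure)
    uf = _UnionFind(nlab + 1)
    # merge components adjacent across the periodic phi seam
    left, right = lab[:, 0, :], lab[:, -1, :]
    n_h, n_r = left.shape
    for dh in (-1, 0, 1):
        for dr in (-1, 0, 1):
            h0, h1 = max(0, dh), min(n_h, n_h + dh)
            r0, r1 = max(0, dr), min(n_r, n_r + dr)
            a = right[h0:h1, r0:r1]
            b = left[h0 - dh : h1 - dh, r0 - dr : r1 - dr]
            both = (a > 0) & (b > 0)
            for pa, pb in set(zip(a[both].tolist(), b[both].tolist())):
                uf.union(pa, pb)
    roots = np.array([uf.find(i) for i in range(nlab + 1)])
    root_lab = roots[lab]
    keep = np.unique(root_lab[hard])
    return np.isin(root_lab, keep[keep > 0])


def median_filter_3d(labels: np.ndarray, size: int = 3) -> np.ndarray:
    """Majority vote over a ``size``^3 neighbourhood of binary labels,
    phi-periodic and replicate-padded in h and r."""
    if size % 2 != 1 or size < 1:
        raise ValueError("kernel size must be odd and positive")
    if size == 1:
        return np.asarray(labels, dtype=bool).copy()
    k = size // 2
    padded = _pad(np.asarray(labels, dtype=np.uint8), (k, k, k))
    win = np.lib.stride_tricks.sliding_window_view(padded, (size, size, size))
    counts = win.sum(axis=(-3, -2, -1), dtype=np.int32)
    return counts > (size**3) // 2


def extract_layer_edges(labels: np.ndarray, exclusion: np.ndarray | None = None) -> SegmentedLayer:
    """First/last ice r-index and ice voxel count along each radial ray.

    Excluded (h, phi) locations carry the :data:`EMPTY` sentinel and a
    count of zero.
    """
    labels = np.asarray(labels, dtype=bool)
    n_h, n_phi, n_r = labels.shape
    if exclusion is None:
        exclusion = np.zeros((n_h, n_phi), dtype=bool)
    if exclusion.shape != (n_h, n_phi):
        raise ValueError("exclusion mask shape must be (n_h, n_phi)")
    any_ice = labels.any(axis=2)
    first = np.where(any_ice, labels.argmax(axis=2), EMPTY)
    last = np.where(any_ice, n_r - 1 - labels[:, :, ::-1].argmax(axis=2), EMPTY)
    count = labels.sum(axis=2)
    use = any_ice & ~exclusion
    first = np.where(use, first, EMPTY)
    last = np.where(use, last, EMPTY)
    count = np.where(~exclusion, count, 0)
    return SegmentedLayer(labels=labels, first=first, last=last, count=count, exclusion=exclusion)


# 1D Sobel-Feldman factors: derivative [-1, 0, 1], smoothing [1, 2, 1]
_DERIV = np.array([-1.0, 0.0, 1.0])
_SMOOTH = np.array([1.0, 2.0, 1.0])


def _sobel_feldman(data: np.ndarray, axis: int) -> np.ndarray:
    """3x3x3 Sobel-Feldman derivative along ``axis`` of an (h, phi, r)
    field, phi-periodic, replicated at h/r boundaries."""
    padded = _pad(np.asarray(data, dtype=float), (1, 1, 1))
    out = padded
    for ax in range(3):
        k = _DERIV if ax == axis else _SMOOTH
        out = ndimage.correlate1d(out, k, axis=ax, mode="constant")
    return out[1:-1, 1:-1, 1:-1]


def surface_normal_angles(vol, grad_floor: float = 1e-6) -> AngleField:
    """Angle between the local surface normal and the radial axis.

    The gradient of the field (grey values or labels) is estimated with
    the 3x3x3 Sobel-Feldman operator per axis; the angle is
    ``arccos(|g_r| / |g|)`` in degrees, so inner and outer surfaces of the
    layer give the same angle.  Voxels with gradient magnitude below
    ``grad_floor`` are flagged invalid.
    """
    data = _data_of(vol).astype(float)
    g_h = _sobel_feldman(data, 0)
    g_p = _sobel_feldman(data, 1)
    g_r = _sobel_feldman(data, 2)
    norm = np.sqrt(g_h**2 + g_p**2 + g_r**2)
    valid = norm >= grad_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.clip(np.abs(g_r) / np.where(valid, norm, 1.0), 0.0, 1.0)
    angle = np.degrees(np.arccos(ratio))
    angle[~valid] = np.nan
    return AngleField(angle_deg=angle, valid=valid)


def build_exclusion_mask(
    shape: tuple[int, int],
    regions: list[tuple] | None,
) -> np.ndarray:
    """Boolean (n_h, n_phi) mask, True where analysis is excluded.

    Each region is either a height band ``(h_lo, h_hi)`` covering all
    azimuths or a rectangle ``(h_lo, h_hi, phi_lo, phi_hi)``, as
    half-open index ranges.  Overlaps union; out-of-grid regions raise.
    """
    n_h, n_phi = shape
    mask = np.zeros(shape, dtype=bool)
    for reg in regions or []:
        if len(reg) == 2:
            h_lo, h_hi = reg
            p_lo, p_hi = 0, n_phi
        elif len(reg) == 4:
            h_lo, h_hi, p_lo, p_hi = reg
        else:
            raise ValueError(f"region must have 2 or 4 entries, got {reg}")
        if not (0 <= h_lo < h_hi <= n_h and 0 <= p_lo < p_hi <= n_phi):
            raise ValueError(f"region {reg} lies outside the ({n_h}, {n_phi}) grid")
        mask[h_lo:h_hi, p_lo:p_hi] = True
    return mask
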