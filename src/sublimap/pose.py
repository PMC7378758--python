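"""Vial axis (pose) estimation from a single reconstructed volume.

Vials are never mounted perfectly centred and upright, so before any
cylindrical analysis the axis of the glass vial is estimated directly from
the reconstruction: at a number of heights a horizontal slice is segmented
with a grey window that isolates the glass wall, edge pixels are ranked by
the magnitude of their radial intensity gradient (taken with respect to the
slice centre) and only the top fraction is kept, a randomized Hough
transform (RHT) over random pixel triplets detects the dominant circle of
each slice, and a vote-count-weighted principal-axis fit through the
detected circle centres yields the 3D axis.

The RHT accumulator uses 1-voxel bins in (cx, cy, r); votes in the winning
bin and its immediate neighbours are averaged, which recovers the centre to
sub-voxel precision on clean data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "NoVialInSliceError",
    "DegenerateTripletError",
    "CircleDetection",
    "VialPose",
    "segment_vial_slice",
    "select_gradient_edges",
    "circumcircle",
    "rht_detect_circle",
    "fit_axis",
    "estimate_pose",
    "pose_repeatability",
]


class NoVialInSliceError(ValueError):
    """The grey window matched no pixel in the slice."""


class DegenerateTripletError(ValueError):
    """The three points are (near-)collinear and define no circle."""


@dataclass(frozen=True)
class CircleDetection:
    """Most significant circle found in one horizontal slice.

    Centre and radius are in the units of the points handed to the RHT
    (pixels for raw slices, um after conversion); ``height_index`` is the
    slice's z index and ``votes`` the accumulator count backing it.
    """

    height_index: int
    center: tuple[float, float]  # (x, y)
    radius: float
    votes: int

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("circle radius must be > 0")
        if self.votes < 1:
            raise ValueError("vote count must be >= 1")


@dataclass
class VialPose:
    """Estimated vial axis: a point on the axis and a unit direction.

    ``point`` and ``direction`` are world (x, y, z) um; direction points
    toward increasing height.  The per-slice detections and their vote
    weights that produced the fit are retained.
    """

    point: np.ndarray
    direction: np.ndarray
    detections: list[CircleDetection] = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"axis direction must be a unit vector, |d| = {n}")

    def axis_xy_at_z(self, z_um) -> np.ndarray:
        """Axis intersection (x, y) with the horizontal plane at height z."""
        s = (np.asarray(z_um, dtype=float) - self.point[2]) / self.direction[2]
        return np.stack(
            [self.point[0] + s * self.direction[0], self.point[1] + s * self.direction[1]],
            axis=-1,
        )


def segment_vial_slice(slice2d: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Binary mask of pixels whose value lies within the glass grey window."""
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"grey window must satisfy lo < hi, got {window}")
    mask = (slice2d >= lo) & (slice2d <= hi)
    if not mask.any():
        raise NoVialInSliceError("grey window matched no pixel: no vial in slice")
    return mask


def select_gradient_edges(
    slice2d: np.ndarray,
    retain_fraction: float,
    mask: np.ndarray | None = None,
    smooth_sigma: float = 1.0,
    center: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the candidate pixels with the strongest radial gradient.

    The gradient is taken with central differences on a Gaussian-smoothed
    copy of the slice and projected on the ray from the slice centre
    (radially outward).  Exactly ``ceil(retain_fraction * N)`` of the N
    candidate pixels (the ``mask`` pixels, or all pixels) are returned,
    ranked by absolute radial gradient; ties break by lexicographic
    (row, col) order for determinism.

    Returns ``(points, weights)``: points as an (n, 2) integer array of
    (row, col) and the matching absolute radial gradients.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    sl = np.asarray(slice2d, dtype=float)
    smooth = ndimage.gaussian_filter(sl, smooth_sigma) if smooth_sigma > 0 else sl
    gy, gx = np.gradient(smooth)
    ny, nx = sl.shape
    cy, cx = center if center is not None else ((ny - 1) / 2.0, (nx - 1) / 2.0)
    yy = np.arange(ny)[:, None] - cy
    xx = np.arange(nx)[None, :] - cx
    rr = np.hypot(yy, xx)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_rad = np.where(rr > 0, (gy * yy + gx * xx) / np.where(rr > 0, rr, 1.0), 0.0)
    if mask is not None:
        rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    else:
        rows, cols = np.nonzero(np.ones_like(sl, dtype=bool))
    if rows.size == 0:
        raise ValueError("no candidate edge points")
    w = np.abs(g_rad[rows, cols])
    k = math.ceil(retain_fraction * rows.size)
    order = np.lexsort((cols, rows, -w))[:k]
    pts = np.stack([rows[order], cols[order]], axis=1)
    return pts, w[order]


def circumcircle(p1, p2, p3, area_tol: float = 1e-6) -> tuple[tuple[float, float], float]:
    """Exact circumscribed circle of three points ``(x, y)``.

    Raises :class:`DegenerateTripletError` when the triangle area is below
    ``area_tol`` (collinear points).
    """
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    if abs(d) < 4.0 * area_tol:  # |d| = 4 * triangle area
        raise DegenerateTripletError("collinear triplet defines no circle")
    s1, s2, s3 = x1 * x1 + y1 * y1, x2 * x2 + y2 * y2, x3 * x3 + y3 * y3
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = math.hypot(x1 - ux, y1 - uy)
    return (ux, uy), r


def _circumcircles_batch(pts: np.ndarray, area_tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised circumcircles for triplets ``pts`` of shape (n, 3, 2).

    Returns (centers (n,2), radii (n,), valid (n,)) with invalid =
    degenerate triplets."""
    x1, y1 = pts[:, 0, 0], pts[:, 0, 1]
    x2, y2 = pts[:, 1, 0], pts[:, 1, 1]
    x3, y3 = pts[:, 2, 0], pts[:, 2, 1]
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    valid = np.abs(d) >= 4.0 * area_tol
    d_safe = np.where(valid, d, 1.0)
    s1, s2, s3 = x1 * x1 + y1 * y1, x2 * x2 + y2 * y2, x3 * x3 + y3 * y3
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d_safe
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d_safe
    r = np.hypot(x1 - ux, y1 - uy)
    return np.stack([ux, uy], axis=1), r, valid


def rht_detect_circle(
    points: np.ndarray,
    n_triplets: int = 5000,
    bin_width: float = 1.0,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    height_index: int = 0,
    area_tol: float = 1e-6,
    max_attempts: int = 50,
) -> CircleDetection:
    """Randomized Hough transform circle detection.

    ``n_triplets`` non-degenerate random triplets of ``points`` (an (n, 2)
    array of (x, y)) each vote for their circumscribed circle; votes are
    accumulated in ``bin_width``-wide bins of (cx, cy, r).  The candidate
    bin with the highest count over its 3x3x3 bin neighbourhood wins (ties
    break toward larger radius, then lexicographic centre) and the returned
    circle is the mean of the votes in that neighbourhood, with the
    neighbourhood count as ``votes``.  Degenerate triplets are resampled
    and do not count toward ``n_triplets``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("RHT needs at least 3 points")
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    centers = np.empty((0, 2), dtype=float)
    radii = np.empty(0, dtype=float)
    attempts = 0
    n = pts.shape[0]
    while radii.size < n_triplets and attempts < max_attempts:
        need = n_triplets - radii.size
        idx = rng.integers(0, n, size=(int(need * 1.3) + 8, 3))
        distinct = (idx[:, 0] != idx[:, 1]) & (idx[:, 0] != idx[:, 2]) & (idx[:, 1] != idx[:, 2])
        idx = idx[distinct]
        if idx.size:
            c, r, valid = _circumcircles_batch(pts[idx], area_tol)
            centers = np.vstack([centers, c[valid][:need]])
            radii = np.concatenate([radii, r[valid][:need]])
        attempts += 1
    if radii.size == 0:
        raise DegenerateTripletError("all sampled triplets were degenerate")

    keys = np.floor(np.column_stack([centers, radii]) / bin_width).astype(np.int64)
    uniq, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    bin_count = {tuple(k): int(c) for k, c in zip(uniq, counts)}

    def merged_count(k: tuple[int, int, int]) -> int:
        return sum(
            bin_count.get((k[0] + a, k[1] + b, k[2] + c), 0)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
        )

    # winner: highest merged count; ties -> larger radius bin, then lexicographic centre
    best_key = None
    best = None
    for k in map(tuple, uniq):
        score = (merged_count(k), k[2], -k[0], -k[1])
        if best is None or score > best:
            best, best_key = score, k
    nb = np.all(np.abs(uniq - np.asarray(best_key)) <= 1, axis=1)
    sel = nb[inv]
    center = centers[sel].mean(axis=0)
    radius = float(radii[sel].mean())
    return CircleDetection(
        height_index=height_index,
        center=(float(center[0]), float(center[1])),
        radius=radius,
        votes=int(sel.sum()),
    )


def fit_axis(
    detections: list[CircleDetection],
    heights: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> VialPose:
    """Weighted principal-axis fit through per-slice circle centres.

    Each detection contributes a 3D point (cx, cy, height) weighted by its
    vote count; the axis is the principal eigenvector of the weighted
    covariance of those points, through the weighted centroid, with its
    sign fixed toward increasing height.  ``heights`` gives each slice's
    height coordinate (defaults to the detection's ``height_index``);
    ``weights`` overrides the vote counts (zero drops a slice entirely).
    """
    if len(detections) < 2:
        raise ValueError("axis fit needs detections at >= 2 slices")
    if heights is None:
        heights = np.array([d.height_index for d in detections], dtype=float)
    else:
        heights = np.asarray(heights, dtype=float)
    if weights is None:
        w = np.array([d.votes for d in detections], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(detections),) or np.any(w < 0):
            raise ValueError("weights must be one non-negative value per detection")
    pts = np.array([[d.center[0], d.center[1], z] for d, z in zip(detections, heights)])
    used = w > 0
    if used.sum() < 2 or np.unique(heights[used]).size < 2:
        raise ValueError("axis fit needs positive-weight detections at >= 2 distinct heights")
    wp = w[used] / w[used].sum()
    centroid = wp @ pts[used]
    dev = pts[used] - centroid
    cov = (dev * wp[:, None]).T @ dev
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, -1]
    if evals[-1] <= 0:
        raise ValueError("degenerate detections: no principal direction")
    if direction[2] < 0:
        direction = -direction
    elif direction[2] == 0:
        raise ValueError("fitted axis is horizontal; not a vial axis")
    return VialPose(point=centroid, direction=direction, detections=list(detections), weights=w)


def estimate_pose(
    volume,
    window: tuple[float, float],
    n_heights: int = 40,
    retain_fraction: float = 0.10,
    n_triplets: int = 5000,
    bin_width_vox: float = 1.0,
    smooth_sigma: float = 1.0,
    seed: int = 0,
) -> VialPose:
    """Estimate the vial axis of a :class:`~sublimap.volume.CartesianVolume`.

    Slices at ``n_heights`` evenly spaced z indices are processed
    independently (each with its own RNG stream spawned from ``seed``);
    slices where the grey window matches nothing are skipped.  The result
    is in world micrometre coordinates.
    """
    nz = volume.shape[0]
    z_idx = np.unique(np.round(np.linspace(0, nz - 1, n_heights)).astype(int))
    streams = np.random.SeedSequence(seed).spawn(len(z_idx))
    detections: list[CircleDetection] = []
    heights: list[float] = []
    z_coords = volume.axis_coords(0)
    for zi, stream in zip(z_idx, streams):
        sl = volume.data[zi]
        try:
            mask = segment_vial_slice(sl, window)
            pts_rc, _ = select_gradient_edges(sl, retain_fraction, mask=mask, smooth_sigma=smooth_sigma)
        except (NoVialInSliceError, ValueError):
            continue
        pts_xy = np.stack([pts_rc[:, 1].astype(float), pts_rc[:, 0].astype(float)], axis=1)
        if pts_xy.shape[0] < 3:
            continue
        det = rht_detect_circle(
            pts_xy,
            n_triplets=n_triplets,
            bin_width=bin_width_vox,
            seed=np.random.default_rng(stream),
            height_index=int(zi),
        )
        # pixel (col, row) -> world um
        cx = (det.center[0] + 0.5) * volume.spacing - volume.shape[2] * volume.spacing / 2.0
        cy = (det.center[1] + 0.5) * volume.spacing - volume.shape[1] * volume.spacing / 2.0
        detections.append(
            CircleDetection(
                height_index=det.height_index,
                center=(cx, cy),
                radius=det.radius * volume.spacing,
                votes=det.votes,
            )
        )
        heights.append(z_coords[zi])
    if len(detections) < 2:
        raise ValueError("pose estimation found circles in fewer than 2 slices")
    return fit_axis(detections, heights=np.asarray(heights))


def pose_repeatability(
    volume,
    window: tuple[float, float],
    n_repeats: int = 4,
    seeds: list[int] | None = None,
    eval_fractions: tuple[float, ...] = (0.9, 0.5, 0.1),
    **pose_kwargs,
) -> dict:
    """Spread of repeated RHT pose estimates at chosen heights.

    Runs :func:`estimate_pose` ``n_repeats`` times with different seeds and
    reports, per evaluation height (fractions of the volume height, default
    top/middle/bottom), the RMS distance of the axis intersections from
    their mean — the repeatability of the random Hough stage.
    """
    if n_repeats < 2:
        raise ValueError("repeatability needs n_repeats >= 2")
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    lo, hi = volume.extent(0)
    z_eval = np.array([lo + f * (hi - lo) for f in eval_fractions])
    inter = np.empty((n_repeats, len(z_eval), 2))
    for i, s in enumerate(seeds):
        pose = estimate_pose(volume, window, seed=s, **pose_kwargs)
        inter[i] = pose.axis_xy_at_z(z_eval)
    mean = inter.mean(axis=0)
    spread = np.sqrt(((inter - mean) ** 2).sum(axis=2).mean(axis=0))
    return {
        "z_um": z_eval,
        "mean_xy_um": mean,
        "spread_um": spread,
        "intersections_um": inter,
    }
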