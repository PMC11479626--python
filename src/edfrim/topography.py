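"""Robust surface-topography estimation from a plane-by-plane speckled scan.

A single slice-by-slice volume (one speckle, coarse z-sampling) is enough to
recover the surface ``z = Z_s(x, y)`` on which the fluorophores lie:

1. a smooth multiplicative background gain ``a(x, y, z)`` and the background
   noise scale are estimated robustly from a small random voxel subsample;
2. the volume is normalized, ``r = (s - a) / (a * sigma0)``, so background
   voxels are approximately standard normal;
3. voxels above the upper-``pfa`` normal quantile become candidate surface
   points;
4. overlapping windowed quadratic fits with RANSAC classify the candidates
   into surface inliers and outliers (labels fused across windows);
5. the inliers are interpolated with a biharmonic (thin-plate) spline to a
   full-grid height map, and the super-resolved EDF image can be draped
   onto it.

Coordinates are voxel centers in nm: lateral position ``i * dx`` and axial
position taken from the acquired plane positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "BackgroundField",
    "NormalizedVolume",
    "BrightPoints",
    "SurfaceEstimate",
    "TexturedSurface",
    "estimate_background",
    "normalize_volume",
    "detect_bright_points",
    "localize_surface_points",
    "fit_surface_ransac",
    "interpolate_surface",
    "project_onto_surface",
    "estimate_topography",
]


# ---------------------------------------------------------------------------
# background normalization (step 1-2)


@dataclass
class BackgroundField:
    """Separable polynomial gain field fitted to a voxel subsample.

    Lateral degree is low (smooth gain); the axial degree may go up to one
    less than the number of planes — with few, widely spaced planes the
    axial background profile (gain drift plus integrated out-of-focus haze)
    is not well captured by a stiff quadratic, and forcing one bends the
    fit at the extreme planes where it then miscalibrates the detector.
    """

    coeffs: np.ndarray
    degree: int
    shape: tuple[int, int, int]
    degree_z: int | None = None

    @property
    def _deg_z(self) -> int:
        if self.degree_z is not None:
            return self.degree_z
        return min(self.shape[0] - 1, 5)

    def _design(self, iz: np.ndarray, iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
        nz, ny, nx = self.shape
        # normalized coordinates in [-1, 1] for conditioning
        u = 2.0 * ix / max(nx - 1, 1) - 1.0
        v = 2.0 * iy / max(ny - 1, 1) - 1.0
        w = 2.0 * iz / max(nz - 1, 1) - 1.0
        cols = []
        for pz in range(self._deg_z + 1):
            for py in range(self.degree + 1):
                for px in range(self.degree + 1):
                    cols.append((w ** pz) * (v ** py) * (u ** px))
        return np.stack(cols, axis=-1)

    def evaluate(self, iz, iy, ix) -> np.ndarray:
        return self._design(
            np.asarray(iz, float), np.asarray(iy, float), np.asarray(ix, float)
        ) @ self.coeffs

    def evaluate_volume(self) -> np.ndarray:
        # separable accumulation: never materialize the full design matrix
        nz, ny, nx = self.shape
        u = 2.0 * np.arange(nx) / max(nx - 1, 1) - 1.0
        v = 2.0 * np.arange(ny) / max(ny - 1, 1) - 1.0
        w = 2.0 * np.arange(nz) / max(nz - 1, 1) - 1.0
        out = np.zeros(self.shape)
        i = 0
        for pz in range(self._deg_z + 1):
            for py in range(self.degree + 1):
                for px in range(self.degree + 1):
                    out += (
                        self.coeffs[i]
                        * (w ** pz)[:, None, None]
                        * (v ** py)[None, :, None]
                        * (u ** px)[None, None, :]
                    )
                    i += 1
        return out


def estimate_background(
    volume: np.ndarray,
    fraction: float = 1e-3,
    seed: int | None = None,
    degree: int = 2,
    degree_z: int | None = None,
    trim_sigma: float = 2.5,
    n_refits: int = 5,
) -> tuple[BackgroundField, float]:
    """Fit the background gain and noise scale from a random voxel subsample.

    A fraction (default 1/1000) of the voxels is drawn at random and a
    separable polynomial (lateral degree <= ``degree``, axial degree up to
    one less than the plane count) is fitted by one-sided trimmed least
    squares: fluorophore signal only ever *adds* photons, so each refit
    discards voxels brighter than ``trim_sigma`` (2.5) robust standard
    deviations above the fit. A one-sided cut this far out leaves the fit
    essentially unbiased on pure background while rejecting the bright
    tail. The noise scale ``sigma0`` is the normalized median absolute
    deviation of ``s / a`` over the whole subsample.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D (nz, ny, nx)")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not vol.any():
        raise ValueError("all-zero volume: background is degenerate")
    bg = BackgroundField(
        coeffs=np.empty(0), degree=degree, shape=vol.shape, degree_z=degree_z
    )
    n_par = (degree + 1) ** 2 * (bg._deg_z + 1)
    nvox = vol.size
    n_sample = min(max(int(round(fraction * nvox)), 30 * n_par), nvox)
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(nvox, size=n_sample, replace=False)
    iz, iy, ix = np.unravel_index(flat_idx, vol.shape)
    s = vol.ravel()[flat_idx]

    design = bg._design(iz.astype(float), iy.astype(float), ix.astype(float))
    keep = np.ones(n_sample, dtype=bool)
    for _ in range(n_refits):
        coeffs, *_ = np.linalg.lstsq(design[keep], s[keep], rcond=None)
        bright = s - design @ coeffs  # positive where brighter than the fit
        scale = stats.median_abs_deviation(bright[keep], scale="normal")
        keep = bright <= trim_sigma * scale if scale > 0 else bright <= 0.0
    bg.coeffs = coeffs

    a_hat = design @ coeffs
    ok = a_hat > 0
    # MAD over the whole subsample: robust to the bright-signal tail while
    # unbiased on pure background (a trimmed subset would not be)
    ratio = s[ok] / a_hat[ok]
    sigma0 = float(stats.median_abs_deviation(ratio, scale="normal"))
    return bg, sigma0


@dataclass
class NormalizedVolume:
    """Background-normalized volume; background voxels are ~ N(0, 1)."""

    values: np.ndarray = field(repr=False)  # r_hat, masked voxels = -inf
    background_gain: np.ndarray = field(repr=False)
    noise_scale: float
    pfa: float | None
    dx: float
    dy: float
    z_planes: np.ndarray = field(repr=False)  # nm, one per slice


def normalize_volume(
    volume: np.ndarray,
    background: BackgroundField,
    noise_scale: float,
    dx: float,
    dy: float,
    z_planes: Sequence[float],
) -> NormalizedVolume:
    """Exact normalization ``r = (s - a) / (a * sigma0)``.

    Voxels where the fitted gain is non-positive are masked (set to -inf)
    rather than divided.
    """
    vol = np.asarray(volume, dtype=float)
    a = background.evaluate_volume()
    r = np.full_like(vol, -np.inf)
    ok = a > 0
    r[ok] = (vol[ok] - a[ok]) / (a[ok] * noise_scale)
    return NormalizedVolume(
        values=r,
        background_gain=a,
        noise_scale=float(noise_scale),
        pfa=None,
        dx=float(dx),
        dy=float(dy),
        z_planes=np.asarray(z_planes, dtype=float),
    )


# ---------------------------------------------------------------------------
# detection (step 3)


@dataclass
class BrightPoints:
    """Candidate surface points (voxel centers, nm) with their r-values."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    value: np.ndarray

    def __len__(self) -> int:
        return self.x.size


def detect_bright_points(normalized: NormalizedVolume, pfa: float = 0.01) -> BrightPoints:
    """Threshold the normalized volume at the upper-``pfa`` normal quantile.

    With a well-normalized background the fraction of background voxels
    crossing the threshold equals ``pfa`` by construction.
    """
    if not 0 < pfa < 0.5:
        raise ValueError("pfa must be in (0, 0.5)")
    threshold = float(stats.norm.isf(pfa))
    iz, iy, ix = np.nonzero(normalized.values > threshold)
    return BrightPoints(
        x=ix * normalized.dx,
        y=iy * normalized.dy,
        z=normalized.z_planes[iz],
        value=normalized.values[iz, iy, ix],
    )


def localize_surface_points(
    normalized: NormalizedVolume,
    pfa: float = 0.01,
    axial_window: float | None = None,
) -> BrightPoints:
    """Detect bright voxels and localize their axial position per column.

    With coarse plane spacing a surface point is detected in the planes
    within the defocus capture range, at the plane's quantized z. The
    clipped-squared-intensity axial centroid over the planes within
    ``axial_window`` (nm) of each column's brightest plane restores a
    sub-plane-spacing height estimate; the window keeps distant defocus
    haze from dragging the centroid when planes are finely spaced. Columns
    with no detection contribute no point. The default window admits the
    immediately adjacent plane (1.1 x the plane spacing) but never less
    than the defocus capture scale (~800 nm at NA 0.8).
    """
    if not 0 < pfa < 0.5:
        raise ValueError("pfa must be in (0, 0.5)")
    if axial_window is None:
        spacing = np.diff(np.sort(np.unique(normalized.z_planes)))
        axial_window = max(800.0, 1.1 * float(np.median(spacing))) if spacing.size else 800.0
    threshold = float(stats.norm.isf(pfa))
    vals = normalized.values
    hit = (vals > threshold).any(axis=0)
    peak_z = normalized.z_planes[np.argmax(vals, axis=0)]
    w = np.clip(vals, 0.0, None) ** 2
    in_window = (
        np.abs(normalized.z_planes[:, None, None] - peak_z[None]) <= axial_window
    )
    w = np.where(in_window, w, 0.0)
    weight = w.sum(axis=0)
    zw = np.einsum("zyx,z->yx", w, normalized.z_planes)
    ok = hit & (weight > 0)
    iy, ix = np.nonzero(ok)
    return BrightPoints(
        x=ix * normalized.dx,
        y=iy * normalized.dy,
        z=zw[ok] / weight[ok],
        value=vals.max(axis=0)[ok],
    )


# ---------------------------------------------------------------------------
# RANSAC windowed quadratic fits (step 4)


def _quad_design(x: np.ndarray, y: np.ndarray, center, halfwidth) -> np.ndarray:
    u = (x - center[0]) / halfwidth[0]
    v = (y - center[1]) / halfwidth[1]
    return np.stack([np.ones_like(u), u, v, u * u, u * v, v * v], axis=-1)


@dataclass
class WindowFit:
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]
    coeffs: np.ndarray | None  # None when the window had too few points
    inlier_mask: np.ndarray | None = None  # over the window's point subset
    point_index: np.ndarray | None = None  # indices into the full point set


@dataclass
class RansacSurfaceFit:
    labels: np.ndarray  # bool, inlier per point
    covered: np.ndarray  # bool, point lay in at least one fitted window
    window_fits: list[WindowFit]


def fit_surface_ransac(
    points: BrightPoints,
    n_windows: tuple[int, int] = (16, 16),
    inlier_tol: float | None = None,
    n_iters: int = 300,
    seed: int | None = None,
    fuse: str = "intersection",
    min_points: int = 6,
) -> RansacSurfaceFit:
    """Classify candidate points into surface inliers/outliers.

    The lateral extent is tiled with ``n_windows`` overlapping windows (50%
    overlap). In each window, RANSAC repeatedly fits ``z = quadratic(x, y)``
    to minimal 6-point samples and keeps the most consensual fit (points
    within ``inlier_tol`` of the surface, default 175 nm = 2x the reference
    axial voxel pitch); the consensus fit is then refined by least squares
    on its inliers. Labels are fused across overlapping windows: with
    ``fuse="intersection"`` (default) a point is an inlier only if every
    fitted window covering it agrees; ``fuse="union"`` accepts any.

    When the points carry detection strengths (``points.value``), consensus
    scoring and the refit are weighted by the excess of each point's value
    over its minimum: with coarsely z-sampled volumes many detections sit at
    the quantized plane height of a *defocused* crossing, and an unweighted
    count lets a degenerate in-plane fit (all residuals exactly zero) beat
    the true surface; brightness weighting anchors the consensus on the
    in-focus points where the surface actually crosses the planes.

    Deterministic for a given seed and invariant to point order.
    """
    n = len(points)
    if n < min_points:
        raise ValueError(f"need at least {min_points} points")
    if fuse not in ("intersection", "union"):
        raise ValueError("fuse must be 'intersection' or 'union'")
    # canonical order so the labels do not depend on input ordering
    order = np.lexsort((points.z, points.y, points.x))
    x, y, z = points.x[order], points.y[order], points.z[order]
    if points.value is not None and np.ptp(points.value) > 0:
        pw = np.clip(points.value[order] - points.value.min(), 0.0, None)
    else:
        pw = np.ones(n)

    if inlier_tol is None:
        inlier_tol = 175.0  # 2 x the reference axial voxel pitch (87.5 nm)

    nwx, nwy = n_windows
    x0, x1 = float(x.min()), float(x.max())
    y0, y1 = float(y.min()), float(y.max())
    wx = 2.0 * (x1 - x0) / (nwx + 1) if nwx > 1 else (x1 - x0)
    wy = 2.0 * (y1 - y0) / (nwy + 1) if nwy > 1 else (y1 - y0)
    wx = wx or 1.0
    wy = wy or 1.0

    ss = np.random.SeedSequence(seed)
    window_seeds = ss.spawn(nwx * nwy)

    inlier_votes = np.zeros(n, dtype=int)
    outlier_votes = np.zeros(n, dtype=int)
    fits: list[WindowFit] = []
    for jy in range(nwy):
        for jx in range(nwx):
            xa = x0 + jx * wx / 2.0
            ya = y0 + jy * wy / 2.0
            xb, yb = xa + wx, ya + wy
            sub = np.nonzero((x >= xa) & (x <= xb) & (y >= ya) & (y <= yb))[0]
            fit = WindowFit((xa, xb), (ya, yb), None, point_index=sub)
            fits.append(fit)
            if sub.size < min_points:
                continue  # too sparse: neighbors cover these points
            rng = np.random.default_rng(window_seeds[jy * nwx + jx])
            center = ((xa + xb) / 2, (ya + yb) / 2)
            halfwidth = (wx / 2, wy / 2)
            a_mat = _quad_design(x[sub], y[sub], center, halfwidth)
            zs = z[sub]
            # draw minimal samples with probability proportional to the
            # brightness weight: with a heavy haze/false-alarm fraction an
            # unweighted 6-point sample is almost never all-surface
            p = pw[sub] / pw[sub].sum() if pw[sub].sum() > 0 else None
            draws = rng.choice(sub.size, size=(n_iters, 6), p=p)
            m = a_mat[draws]  # (iters, 6, 6)
            rhs = zs[draws]
            # tiny ridge guards degenerate minimal samples
            m = m + 1e-9 * np.eye(6)[None]
            try:
                cand = np.linalg.solve(m, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                keep_rows = []
                cand = np.zeros((n_iters, 6))
                for i in range(n_iters):
                    try:
                        cand[i] = np.linalg.solve(m[i], rhs[i])
                        keep_rows.append(i)
                    except np.linalg.LinAlgError:
                        cand[i] = np.nan
            ws = pw[sub]
            resid = np.abs(a_mat @ cand.T - zs[:, None])

            scores = ws @ (resid < inlier_tol)
            scores[~np.isfinite(cand).all(axis=1)] = -1.0
            best = int(np.argmax(scores))
            inliers = resid[:, best] < inlier_tol
            # refine by weighted least squares on the consensus set
            for _ in range(3):
                if inliers.sum() < min_points:
                    break
                sw = np.sqrt(ws[inliers])
                coeffs, *_ = np.linalg.lstsq(
                    a_mat[inliers] * sw[:, None], zs[inliers] * sw, rcond=None
                )
                inliers = np.abs(a_mat @ coeffs - zs) < inlier_tol
            if inliers.sum() < min_points:
                continue
            fit.coeffs = coeffs
            fit.inlier_mask = inliers
            inlier_votes[sub[inliers]] += 1
            outlier_votes[sub[~inliers]] += 1

    covered_sorted = (inlier_votes + outlier_votes) > 0
    if fuse == "intersection":
        labels_sorted = covered_sorted & (outlier_votes == 0)
    else:
        labels_sorted = inlier_votes > 0

    labels = np.zeros(n, dtype=bool)
    covered = np.zeros(n, dtype=bool)
    labels[order] = labels_sorted
    covered[order] = covered_sorted
    return RansacSurfaceFit(labels=labels, covered=covered, window_fits=fits)


def consolidate_points(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    weight: np.ndarray | None,
    tile_nm: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge nearby surface points into weighted centroid anchors.

    Inlier heights are quantized by the acquisition planes: each detection
    carries the plane height, exact only on the locus where the surface
    actually crosses that plane. Averaging the points inside lateral tiles
    of ``tile_nm`` produces anchors whose lateral position is the local
    crossing centroid — where the quantized height *is* the surface height —
    so the consolidated anchors are far more accurate than any single
    detection. Tiles should stay small against the surface curvature scale.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    tx = np.floor(x / tile_nm).astype(np.int64)
    ty = np.floor(y / tile_nm).astype(np.int64)
    key = tx * (ty.max() + 2) + ty
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    w = np.ones_like(z) if weight is None else np.asarray(weight, float)
    uniq, start = np.unique(key_s, return_index=True)
    sums = np.add.reduceat((w)[order], start)
    xa = np.add.reduceat((w * x)[order], start) / sums
    ya = np.add.reduceat((w * y)[order], start) / sums
    za = np.add.reduceat((w * z)[order], start) / sums
    return xa, ya, za


def filter_anchor_outliers(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    k: int = 12,
    threshold_nm: float = 600.0,
    n_passes: int = 2,
) -> np.ndarray:
    """Drop anchors inconsistent with a local plane through their neighbors.

    A single-valued surface is locally planar at the anchor spacing scale;
    an anchor whose height deviates from the least-squares plane through
    its ``k`` nearest (surviving) neighbors by more than ``threshold_nm``
    is a residual artifact cluster, not surface. Returns a keep-mask.
    """
    from scipy.spatial import cKDTree

    keep = np.ones(x.size, dtype=bool)
    for _ in range(n_passes):
        idx = np.nonzero(keep)[0]
        if idx.size < k + 1:
            break
        tree = cKDTree(np.column_stack([x[idx], y[idx]]))
        _, nb = tree.query(np.column_stack([x[idx], y[idx]]), k=k + 1)
        drop = np.zeros(idx.size, dtype=bool)
        for j in range(idx.size):
            nbj = idx[nb[j, 1:]]
            a = np.column_stack([x[nbj], y[nbj], np.ones(nbj.size)])
            coef, *_ = np.linalg.lstsq(a, z[nbj], rcond=None)
            pred = coef[0] * x[idx[j]] + coef[1] * y[idx[j]] + coef[2]
            drop[j] = abs(z[idx[j]] - pred) > threshold_nm
        if not drop.any():
            break
        keep[idx[drop]] = False
    return keep


# ---------------------------------------------------------------------------
# interpolation and projection (step 5)


@dataclass
class SurfaceEstimate:
    """Estimated height map with the points that produced it."""

    z_grid: np.ndarray = field(repr=False)  # (ny, nx), nm
    valid_mask: np.ndarray = field(repr=False)  # inside the inlier hull
    points: BrightPoints = field(repr=False)
    labels: np.ndarray = field(repr=False)
    window_fits: list[WindowFit] = field(repr=False, default_factory=list)


def interpolate_surface(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    shape: tuple[int, int],
    dx: float,
    dy: float,
    neighbors: int | None = None,
    smoothing: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Biharmonic (thin-plate spline) interpolation of inliers to the grid.

    Returns ``(z_grid, valid_mask)`` where the mask flags pixels inside the
    convex hull of the points (the spline extrapolates smoothly outside but
    those values are unconstrained). Duplicate lateral sites are collapsed
    to their mean height before interpolation. For large point sets a local
    spline (``neighbors`` nearest centres, default 32 above 1500 points) is
    used; it still passes through the data sites.
    """
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    zz = np.asarray(z, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    # collapse duplicate (x, y) sites, averaging z
    uniq, inv = np.unique(pts, axis=0, return_inverse=True)
    if uniq.shape[0] != pts.shape[0]:
        sums = np.zeros(uniq.shape[0])
        counts = np.zeros(uniq.shape[0])
        np.add.at(sums, inv, zz)
        np.add.at(counts, inv, 1.0)
        pts, zz = uniq, sums / counts
    if pts.shape[0] < 3 or np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
        raise ValueError("degenerate point geometry (collinear or too few)")
    if neighbors is None and pts.shape[0] > 1500:
        neighbors = 32
    interp = RBFInterpolator(
        pts, zz, kernel="thin_plate_spline", smoothing=smoothing, neighbors=neighbors
    )
    ny, nx = shape
    gx = np.arange(nx) * dx
    gy = np.arange(ny) * dy
    query = np.column_stack(
        [np.tile(gx, ny), np.repeat(gy, nx)]
    )
    z_grid = interp(query).reshape(ny, nx)
    try:
        hull = Delaunay(pts)
        valid = (hull.find_simplex(query) >= 0).reshape(ny, nx)
    except QhullError:
        valid = np.zeros(shape, dtype=bool)
    return z_grid, valid


@dataclass
class TexturedSurface:
    """Vertex grid (x, y, Z_s) with per-vertex intensity from the EDF image."""

    vertices: np.ndarray = field(repr=False)  # (ny, nx, 3) in nm
    intensity: np.ndarray = field(repr=False)  # (ny, nx)


def project_onto_surface(
    edf_image: np.ndarray, z_grid: np.ndarray, dx: float, dy: float
) -> TexturedSurface:
    """Drape the (super-resolved) EDF image onto the estimated topography.

    Intensities pass through unchanged; only geometry is added.
    """
    img = np.asarray(edf_image, dtype=float)
    zg = np.asarray(z_grid, dtype=float)
    if img.shape != zg.shape:
        raise ValueError("image and height map shapes differ")
    ny, nx = img.shape
    xx = np.arange(nx)[None, :] * dx * np.ones((ny, 1))
    yy = np.arange(ny)[:, None] * dy * np.ones((1, nx))
    vertices = np.stack([xx, yy, zg], axis=-1)
    return TexturedSurface(vertices=vertices, intensity=img.copy())


# ---------------------------------------------------------------------------
# end-to-end


def estimate_topography(
    volume: np.ndarray,
    dx: float,
    dy: float,
    z_planes: Sequence[float],
    pfa: float = 0.01,
    fraction: float = 1e-3,
    n_windows: tuple[int, int] = (16, 16),
    inlier_tol: float | None = None,
    n_iters: int = 300,
    seed: int | None = None,
    fuse: str = "intersection",
    refine_z: bool = True,
    consolidate_tile_nm: float | None = 600.0,
) -> SurfaceEstimate:
    """Full pipeline: background -> normalize -> detect -> RANSAC -> spline.

    ``refine_z`` (default) replaces raw quantized detections by per-column
    intensity-weighted axial centroids (:func:`localize_surface_points`);
    ``consolidate_tile_nm`` merges the surviving inliers into local
    centroid anchors before spline interpolation (None disables).
    """
    bg, sigma0 = estimate_background(volume, fraction=fraction, seed=seed)
    norm = normalize_volume(volume, bg, sigma0, dx, dy, z_planes)
    if refine_z:
        pts = localize_surface_points(norm, pfa=pfa)
    else:
        pts = detect_bright_points(norm, pfa=pfa)
    fit = fit_surface_ransac(
        pts,
        n_windows=n_windows,
        inlier_tol=inlier_tol,
        n_iters=n_iters,
        seed=seed,
        fuse=fuse,
    )
    keep = fit.labels
    xk, yk, zk = pts.x[keep], pts.y[keep], pts.z[keep]
    if consolidate_tile_nm:
        vk = pts.value[keep] - pts.value.min()
        xk, yk, zk = consolidate_points(xk, yk, zk, vk, consolidate_tile_nm)
        ok = filter_anchor_outliers(xk, yk, zk)
        xk, yk, zk = xk[ok], yk[ok], zk[ok]
    z_grid, valid = interpolate_surface(
        xk, yk, zk, volume.shape[1:], dx, dy
    )
    return SurfaceEstimate(
        z_grid=z_grid,
        valid_mask=valid,
        points=pts,
        labels=fit.labels,
        window_fits=fit.window_fits,
    )
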