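"""Superficial/deep volume separation via a fitted separation surface.

Wound healing is driven by the superficial capillary plexus, so each
volume is split into a superficial and a deep compartment.  The skin
surface is not planar, hence the separation cannot be a flat plane:

1. compute the maximum-amplitude projection and its depth index;
2. apply multiscale (Frangi) vessel enhancement at fine and coarse
   scales to boost small and large vessels differentially;
3. keep the depth indices of pixels containing small but not large
   vessels as support points — these sit *on* superficial capillaries;
4. fit a continuous surface to the support points twice — a scattered
   linear interpolation (accurate but noisy) and a fifth-order bivariate
   polynomial (smooth) — and average the two, then shift the average
   down by a configurable offset so it passes *between* the layers;
5. split the volume voxel-wise at the surface; superficial + deep
   reproduce the original exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from scipy.optimize import least_squares
from skimage.filters import frangi

from .containers import Projection, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "VesselnessMaps",
    "SeparationSurface",
    "multiscale_vesselness",
    "compute_vesselness_maps",
    "select_support_points",
    "fit_separation_surface",
    "split_volume",
]

SMALL_SCALES = (5.0, 10.0, 15.0)  # µm, matching 10–30 µm capillaries
LARGE_SCALES = (25.0, 40.0, 60.0)  # µm, matching 35–50 µm deep vessels


@dataclass
class VesselnessMaps:
    """Fine- and coarse-scale tubularity responses of one projection."""

    small: np.ndarray
    large: np.ndarray
    scales_small: tuple[float, ...] = SMALL_SCALES
    scales_large: tuple[float, ...] = LARGE_SCALES


@dataclass
class SeparationSurface:
    """2D grid of depths (µm) separating superficial from deep vessels."""

    depth: np.ndarray  # (ny, nx) µm
    support_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    method: str = "average"
    pixel: tuple[float, float] = (1.0, 1.0)


def multiscale_vesselness(
    map_2d: np.ndarray,
    scales: tuple[float, ...],
    pixel: float = 1.0,
    gamma: float = 0.01,
) -> np.ndarray:
    """Frangi tubularity of a projection, maximum over scales.

    ``scales`` are approximate vessel diameters in µm; the Gaussian scale
    of the Hessian is half that (for a Gaussian tube of radius r the
    ridge response peaks near σ ≈ r/2·…·r, and σ = scale/2 matches the
    layer diameter regimes).  Bright ridges on dark background; a
    constant image returns zero everywhere.  ``gamma`` (the structureness
    scale) is fixed rather than derived per scale, so responses remain
    comparable *across* scales — an auto-tuned gamma renormalizes each
    scale and erases the selectivity the layer gating relies on.  The
    default suits amplitude maps normalized to [0, 1].
    """
    if len(scales) == 0:
        raise ValueError("need at least one scale")
    img = np.asarray(map_2d, dtype=float)
    if min(scales) <= 0:
        raise ValueError("scales must be positive")
    if max(scales) > min(img.shape) * pixel / 4:
        raise ValueError("scales must be below a quarter of the image extent")
    if img.max() == img.min():
        return np.zeros_like(img)
    sigmas = [max(s / (2.0 * pixel), 0.5) for s in scales]
    resp = frangi(img, sigmas=sigmas, beta=0.5, gamma=gamma, black_ridges=False)
    return np.clip(resp, 0.0, None)


def compute_vesselness_maps(
    map_2d: np.ndarray,
    pixel: float,
    scales_small: tuple[float, ...] = SMALL_SCALES,
    scales_large: tuple[float, ...] = LARGE_SCALES,
) -> VesselnessMaps:
    """Fine and coarse vesselness of the same (CLAHE) projection."""
    return VesselnessMaps(
        small=multiscale_vesselness(map_2d, scales_small, pixel),
        large=multiscale_vesselness(map_2d, scales_large, pixel),
        scales_small=tuple(scales_small),
        scales_large=tuple(scales_large),
    )


def select_support_points(
    vn: VesselnessMaps,
    proj: Projection,
    q_small: float = 0.9,
    q_large: float = 0.7,
    min_amplitude: float = 0.25,
    min_points: int = 50,
    depth_tolerance: float = 35.0,
    max_persistence: float = 0.32,
) -> np.ndarray:
    """Depth samples on small-but-not-large vessel pixels.

    A pixel is a candidate when its fine-scale response exceeds the
    ``q_small`` quantile and its projected amplitude exceeds
    ``min_amplitude`` of the maximum (noise pixels carry a meaningless
    depth index).  Large-vessel pixels are then rejected twice over:

    * width gating — pixels whose amplitude persists under smoothing at
      the coarse scale (wide structures), or whose coarse-scale
      vesselness weighted by that persistence is high, are dropped above
      the ``q_large`` candidate quantile;
    * depth gating — a robust (soft-L1) quadratic surface is pre-fitted
      to the remaining depths and points deeper than the fit by more
      than ``depth_tolerance`` µm are discarded.  Deep vessels run
      ≳80 µm below the capillary plexus, so they separate cleanly in
      depth even when their width is ambiguous.

    Returns (x, y, depth) µm; raises when fewer than ``min_points``
    survive.
    """
    if not (0 < q_small < 1 and 0 < q_large < 1):
        raise ValueError("quantiles must be in (0, 1)")
    amp = np.asarray(proj.map, dtype=float)
    peak = amp.max()
    if peak <= 0:
        raise ValueError("insufficient support: empty projection")
    amp = amp / peak
    cand = vn.small > np.quantile(vn.small, q_small)
    cand &= amp > min_amplitude
    if cand.sum() < min_points:
        raise ValueError(f"insufficient support: {cand.sum()} < {min_points} points")

    dx, dy = proj.pixel
    sigma_px = float(np.median(vn.scales_large)) / 2.0 / dx
    persist = ndimage.gaussian_filter(amp, sigma_px)
    coarse = vn.large * persist
    sel = cand.copy()
    # absolute cap first: a scene of only wide vessels must yield (near) no
    # support, which a purely quantile-based gate cannot express
    sel &= persist < max_persistence
    if sel.any():
        sel &= persist < np.quantile(persist[cand], q_large)
        sel &= coarse < np.quantile(coarse[cand], q_large)

    rows, cols = np.nonzero(sel)
    if len(rows) < min_points:
        raise ValueError(f"insufficient support: {len(rows)} < {min_points} points")
    x = cols * dx
    y = rows * dy
    z = proj.depth_index[rows, cols] * proj.dz

    # robust depth prune: deep-vessel stragglers lie far below the fit
    cx, sx = x.mean(), max(np.ptp(x) / 2, 1.0)
    cy, sy = y.mean(), max(np.ptp(y) / 2, 1.0)
    for _ in range(2):
        if len(x) < min_points:
            break
        A = _poly_design((x - cx) / sx, (y - cy) / sy, 2)
        sol = least_squares(
            lambda c: A @ c - z, np.zeros(A.shape[1]), loss="soft_l1", f_scale=20.0
        )
        keep = z < A @ sol.x + depth_tolerance
        x, y, z = x[keep], y[keep], z[keep]

    if len(x) < min_points:
        raise ValueError(f"insufficient support: {len(x)} < {min_points} points")
    return np.column_stack([x, y, z]).astype(float)


def _poly_design(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [x**i * y**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.column_stack(cols)


def fit_separation_surface(
    points: np.ndarray,
    grid: tuple[int, int, float, float],
    offset: float = 30.0,
    degree: int = 5,
    max_points: int = 4000,
    smoothing_um: float = 250.0,
) -> SeparationSurface:
    """Average of linear-interpolated and degree-5 polynomial surfaces.

    ``grid`` is (nx, ny, dx, dy) of the lateral grid.  Support points sit
    on capillaries *above* the true separation, so the averaged surface
    is shifted deeper by ``offset`` µm (default ≈ 3× the median
    superficial vessel radius).  Outside the convex hull of the support
    the polynomial alone is used.  Coordinates are centered and scaled
    before the polynomial fit for conditioning; a rank-deficient fit
    falls back to a lower degree (logged).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 50:
        raise ValueError("need at least 50 support points")
    nx, ny, dx, dy = grid
    nx, ny = int(nx), int(ny)
    span_x = pts[:, 0].max() - pts[:, 0].min()
    span_y = pts[:, 1].max() - pts[:, 1].min()
    if span_x < 0.5 * nx * dx or span_y < 0.5 * ny * dy:
        raise ValueError("support points must span at least 50% of the grid extent")

    if len(pts) > max_points:
        stride = len(pts) // max_points + 1
        pts_fit = pts[::stride]
    else:
        pts_fit = pts

    xg = np.arange(nx) * dx
    yg = np.arange(ny) * dy
    gx, gy = np.meshgrid(xg, yg)

    interp = LinearNDInterpolator(pts_fit[:, :2], pts_fit[:, 2])
    lin = interp(gx, gy)

    # centered/scaled coordinates for the polynomial fit
    cx, sx = pts[:, 0].mean(), max(span_x / 2, 1.0)
    cy, sy = pts[:, 1].mean(), max(span_y / 2, 1.0)
    deg = degree
    while deg >= 1:
        A = _poly_design((pts_fit[:, 0] - cx) / sx, (pts_fit[:, 1] - cy) / sy, deg)
        coef, _, rank, _ = np.linalg.lstsq(A, pts_fit[:, 2], rcond=None)
        if rank == A.shape[1]:
            break
        logger.warning("rank-deficient degree-%d surface fit; trying degree %d",
                       deg, deg - 1)
        deg -= 1
    Ag = _poly_design((gx.ravel() - cx) / sx, (gy.ravel() - cy) / sy, deg)
    poly = (Ag @ coef).reshape(gy.shape)

    inside = np.isfinite(lin)
    avg = np.where(inside, 0.5 * (lin + poly), np.nan)
    if not inside.all():
        # beyond the support hull a quintic extrapolates wildly; continue
        # the surface with the nearest in-hull value instead
        _, (ri, ci) = ndimage.distance_transform_edt(
            ~inside, return_indices=True, sampling=(dy, dx)
        )
        avg = avg[ri, ci]
    if smoothing_um > 0:
        # the dermal separation varies on the mm scale; sub-mm wiggle in the
        # fit is support-sampling noise, not anatomy
        avg = ndimage.gaussian_filter(
            avg, sigma=(smoothing_um / dy, smoothing_um / dx), mode="nearest"
        )
    return SeparationSurface(
        depth=avg + offset,
        support_points=pts,
        method="average" if deg == degree else f"average(poly{deg})",
        pixel=(dx, dy),
    )


def separate_layers(
    volume: Volume,
    q_small: float = 0.9,
    q_large: float = 0.7,
    offset: float = 30.0,
    scales_small: tuple[float, ...] = SMALL_SCALES,
    scales_large: tuple[float, ...] = LARGE_SCALES,
) -> tuple[Volume, Volume, SeparationSurface]:
    """Full layer-separation stage: MAP → vesselness → surface → split.

    Vesselness for the support gating is computed on the normalized raw
    projection: CLAHE flattens the amplitude contrast between thin and
    wide vessels and with it the scale discrimination the gating needs.
    """
    from .preprocess import max_amplitude_projection

    proj = max_amplitude_projection(volume)
    peak = proj.map.max()
    norm = proj.map / peak if peak > 0 else proj.map
    vn = compute_vesselness_maps(norm, volume.voxel[0], scales_small, scales_large)
    pts = select_support_points(vn, proj, q_small=q_small, q_large=q_large)
    ny, nx = proj.map.shape
    surf = fit_separation_surface(
        pts, (nx, ny, volume.voxel[0], volume.voxel[1]), offset=offset
    )
    sup, deep = split_volume(volume, surf)
    return sup, deep, surf


def split_volume(
    volume: Volume, surface: SeparationSurface
) -> tuple[Volume, Volume]:
    """Split a volume at the separation surface, conserving every voxel.

    A voxel is superficial iff its depth coordinate is strictly less than
    the surface depth at its lateral position; superficial + deep equal
    the original element-wise.
    """
    if surface.depth.shape != volume.data.shape[:2]:
        raise ValueError("surface grid does not match the volume's lateral grid")
    z = volume.z_coords()
    above = z[None, None, :] < surface.depth[:, :, None]
    sup_data = np.where(above, volume.data, 0).astype(volume.data.dtype)
    deep_data = volume.data - sup_data
    sup = Volume(sup_data, volume.voxel, meta={**volume.meta, "layer": "superficial"})
    deep = Volume(deep_data, volume.voxel, meta={**volume.meta, "layer": "deep"})
    return sup, deep
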