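"""Seeded generator of ground-truthed synthetic vascular scenes.

Emulates the statistical structure the analysis assumes: dorsal mouse
skin carries two vascular layers separated by a smooth, non-planar
surface — a superficial plexus of tortuous capillaries (≈10–30 µm
diameter) above, and straighter, larger vessels (≈35–50 µm) below.  A
circular full-thickness wound appears as an avascular disk that shrinks
over days post wounding (dpw), surrounded early on by a ring of tortuous
sprouts and later filled by radially aligned, maturing vessels.

Vessels are rendered as Gaussian-profile tubes,
``amplitude = exp(−d²/2σ²)`` with ``σ = radius/2``, mimicking the
band-limited optoacoustic response of a cylindrical absorber; a voxel is
considered "inside" a vessel when its amplitude is ≥ exp(−2), i.e. within
the nominal radius.  All generators are driven by a single integer seed
and are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .containers import RawScan, Volume
from .vessels import alignment_scores, chord_angle, polyline_length, polyline_tortuosity

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomConfig",
    "WoundSeriesConfig",
    "GroundTruth",
    "make_vessel_phantom",
    "make_wound_series",
    "make_edge_target",
    "make_raw_scan",
    "evaluate_surface",
]

INSIDE_AMPLITUDE = math.exp(-2.0)  # tube boundary: d = 2σ = radius

# default true separation surface: mean depth 250 µm with gentle curvature,
# as polynomial coefficients [c00, c10, c01, c20, c11, c02] in normalized
# lateral coordinates u = x/Lx − 0.5, v = y/Ly − 0.5
DEFAULT_SURFACE_COEFFS = (250.0, 40.0, -30.0, 120.0, 20.0, 80.0)


def evaluate_surface(
    coeffs: tuple[float, ...],
    x_um: np.ndarray,
    y_um: np.ndarray,
    fov: tuple[float, float],
) -> np.ndarray:
    """Evaluate the true separation surface (µm depth) at lateral points."""
    u = np.asarray(x_um) / fov[0] - 0.5
    v = np.asarray(y_um) / fov[1] - 0.5
    c = list(coeffs) + [0.0] * (6 - len(coeffs))
    return c[0] + c[1] * u + c[2] * v + c[3] * u * u + c[4] * u * v + c[5] * v * v


@dataclass
class PhantomConfig:
    """Configuration of a two-layer vascular phantom.

    The default scene is 7 × 7 mm² laterally and 1.5 mm deep at
    10 µm lateral / 5 µm axial voxels; ``full_resolution`` runs cost
    more and are obtained simply by passing a 5 µm lateral voxel.
    """

    field_of_view: tuple[float, float] = (7000.0, 7000.0)  # (x, y) µm
    depth: float = 1500.0  # µm
    voxel: tuple[float, float, float] = (10.0, 10.0, 5.0)  # µm
    superficial_diam_range: tuple[float, float] = (10.0, 30.0)
    deep_diam_range: tuple[float, float] = (35.0, 50.0)
    surface_coeffs: tuple[float, ...] = DEFAULT_SURFACE_COEFFS
    capillary_tortuosity: float = 1.0  # target turning rate °/µm
    vessel_counts: tuple[int, int] = (40, 15)  # (superficial, deep)
    noise_sigma: float = 0.02  # additive Gaussian, amplitude units
    psf_fwhm: tuple[float, float] | None = None  # (lateral, axial) µm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_of_view) <= 0 or self.depth <= 0:
            raise ValueError("all extents must be positive")
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel spacings must be positive")
        lo_s, hi_s = self.superficial_diam_range
        lo_d, hi_d = self.deep_diam_range
        if lo_s <= 0 or lo_d <= 0 or hi_s <= lo_s or hi_d <= lo_d:
            raise ValueError("diameter ranges must be positive and increasing")
        if hi_s > lo_d:
            raise ValueError("layer diameter ranges must not overlap")
        # a tube thinner than two voxels along the finest axis cannot be
        # rasterized faithfully
        min_diam = min(lo_s, lo_d)
        if min_diam < 2.0 * min(self.voxel):
            raise ValueError(
                f"unresolvable vessel: diameter {min_diam} µm < 2 voxels "
                f"({2 * min(self.voxel)} µm)"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        nx = int(round(self.field_of_view[0] / self.voxel[0]))
        ny = int(round(self.field_of_view[1] / self.voxel[1]))
        nz = int(round(self.depth / self.voxel[2]))
        return (ny, nx, nz)


@dataclass
class WoundSeriesConfig:
    """Configuration of a healing wound time series.

    ``closure_logistic`` is (steepness day⁻¹, midpoint day) of the
    closure/vascularization score s(t); the avascular disk covers a
    fraction (1 − s) of the initial wound *area*.  The defaults follow
    full-thickness 5 mm excisional wounds whose cohort re-vascularization
    means are ≈40/72/96/99 % at 5/7/10/13 dpw, i.e. logistic steepness
    0.8 day⁻¹ and midpoint 5.5 day.
    """

    timepoints: tuple[float, ...] = (5.0, 7.0, 10.0, 13.0)  # dpw
    initial_radius: float = 2500.0  # µm (5 mm diameter wounds)
    closure_logistic: tuple[float, float] = (0.8, 5.5)  # (k day⁻¹, t0 day)
    sprout_ring_width: float = 400.0  # µm
    alignment_schedule: dict[float, float] | float = field(
        default_factory=lambda: {5.0: 0.2, 7.0: 0.5, 10.0: 0.8, 13.0: 0.9}
    )
    field_of_view: tuple[float, float] = (7000.0, 7000.0)
    depth: float = 400.0  # shallow single-layer volumes
    voxel: tuple[float, float, float] = (10.0, 10.0, 10.0)
    noise_sigma: float = 0.02
    background_spacing: float = 300.0  # µm jittered-grid pitch (< 2× the
    # 200 µm mask-closing radius, so the network closes into a covered area)
    ring_vessels: int = 90
    radial_spacing: float = 250.0  # µm polar-lattice pitch of in-wound vessels
    walk_step: float = 30.0  # µm centerline step; curvature visible at 10 µm voxels
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.initial_radius <= 0:
            raise ValueError("initial_radius must be positive")

    def alignment_at(self, t: float) -> float:
        if isinstance(self.alignment_schedule, dict):
            keys = sorted(self.alignment_schedule)
            vals = [self.alignment_schedule[k] for k in keys]
            return float(np.interp(t, keys, vals))
        return float(self.alignment_schedule)

    def closure_score(self, t: float) -> float:
        k, t0 = self.closure_logistic
        return float(1.0 / (1.0 + math.exp(-k * (t - t0))))

    def wound_radius(self, t: float) -> float:
        """Avascular disk radius: area shrinks as (1 − score)·initial area."""
        return float(self.initial_radius * math.sqrt(max(0.0, 1.0 - self.closure_score(t))))


@dataclass
class GroundTruth:
    """Generating geometry and per-segment true metrics of a phantom."""

    centerlines: list[dict]  # {"points": (n,3) µm, "radii": (n,), "layer": str}
    true_surface: np.ndarray | None  # (ny, nx) depth µm, or None
    wound_mask: np.ndarray | None  # (ny, nx) bool, avascular region
    wound_center: tuple[float, float] | None
    metrics: pd.DataFrame  # per-segment true length/diameter/tortuosity/angle
    superficial_mask: np.ndarray | None = None  # voxels inside superficial tubes
    deep_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# centerline synthesis


def _kappa_for_turning_rate(rate_deg_per_um: float, step: float) -> float:
    """von Mises concentration giving E|Δθ| = rate·step (radians)."""
    m = math.radians(rate_deg_per_um * step)
    if m <= 1e-9:
        return np.inf
    # for concentrated von Mises, E|Δθ| ≈ sqrt(2/(π κ))
    return 2.0 / (math.pi * m * m)


def _random_walk_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    length: float,
    step: float,
    turning_rate: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """2D random-walk centerline with von-Mises turning increments."""
    n = max(2, int(round(length / step)) + 1)
    kappa = _kappa_for_turning_rate(turning_rate, step)
    pts = np.empty((n, 2))
    pts[0] = start
    h = heading
    for i in range(1, n):
        if np.isfinite(kappa):
            h += rng.vonmises(0.0, kappa)
        pts[i] = pts[i - 1] + step * np.array([math.cos(h), math.sin(h)])
        if bounds is not None:
            x0, x1, y0, y1 = bounds
            if not (x0 <= pts[i, 0] <= x1 and y0 <= pts[i, 1] <= y1):
                return pts[: i + 1]
    return pts


# ---------------------------------------------------------------------------
# rendering


def _render_polyline(
    data: np.ndarray,
    points_um: np.ndarray,
    radii_um: np.ndarray,
    voxel: tuple[float, float, float],
) -> None:
    """Accumulate a Gaussian-profile tube into ``data`` (max-combined)."""
    dx, dy, dz = voxel
    ny, nx, nz = data.shape
    for a in range(len(points_um) - 1):
        p0 = points_um[a]
        p1 = points_um[a + 1]
        r = 0.5 * (radii_um[a] + radii_um[a + 1])
        sigma = r / 2.0
        pad = 2.5 * sigma
        lo = np.minimum(p0, p1) - pad
        hi = np.maximum(p0, p1) + pad
        ix0 = max(0, int(math.floor(lo[0] / dx)))
        ix1 = min(nx, int(math.ceil(hi[0] / dx)) + 1)
        iy0 = max(0, int(math.floor(lo[1] / dy)))
        iy1 = min(ny, int(math.ceil(hi[1] / dy)) + 1)
        iz0 = max(0, int(math.floor(lo[2] / dz)))
        iz1 = min(nz, int(math.ceil(hi[2] / dz)) + 1)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        xs = (np.arange(ix0, ix1) * dx)[None, :, None]
        ys = (np.arange(iy0, iy1) * dy)[:, None, None]
        zs = (np.arange(iz0, iz1) * dz)[None, None, :]
        u = p1 - p0
        uu = float(u @ u)
        qx = xs - p0[0]
        qy = ys - p0[1]
        qz = zs - p0[2]
        if uu <= 1e-12:
            d2 = qx**2 + qy**2 + qz**2
        else:
            t = (qx * u[0] + qy * u[1] + qz * u[2]) / uu
            np.clip(t, 0.0, 1.0, out=t)
            d2 = (qx - t * u[0]) ** 2 + (qy - t * u[1]) ** 2 + (qz - t * u[2]) ** 2
        amp = np.exp(d2 / (-2.0 * sigma * sigma)).astype(data.dtype)
        box = data[iy0:iy1, ix0:ix1, iz0:iz1]
        np.maximum(box, amp, out=box)


def _true_metrics(
    centerlines: list[dict], wound_center: tuple[float, float] | None
) -> pd.DataFrame:
    rows = []
    for cl in centerlines:
        pts = cl["points"]
        row = {
            "layer": cl["layer"],
            "length_um": polyline_length(pts),
            "diameter_um": float(2.0 * np.mean(cl["radii"])),
            "angle_deg": chord_angle(pts),
            "tortuosity_deg_per_um": polyline_tortuosity(pts),
            "midpoint_x_um": float(pts[len(pts) // 2, 0]),
            "midpoint_y_um": float(pts[len(pts) // 2, 1]),
        }
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "layer",
            "length_um",
            "diameter_um",
            "angle_deg",
            "tortuosity_deg_per_um",
            "midpoint_x_um",
            "midpoint_y_um",
        ],
    )
    if wound_center is not None and len(df):
        df["alignment"] = alignment_scores(
            df["angle_deg"].to_numpy(),
            df[["midpoint_x_um", "midpoint_y_um"]].to_numpy(),
            wound_center,
        )
    return df


# ---------------------------------------------------------------------------
# two-layer phantom


def make_vessel_phantom(config: PhantomConfig) -> tuple[Volume, GroundTruth]:
    """Generate a two-layer vascular volume with full ground truth.

    Superficial capillaries run 25–60 µm above the true separation
    surface; deep vessels 80–250 µm below it.  True per-segment metrics
    are computed from the generating polylines, never from the raster.
    """
    rng = np.random.default_rng(config.seed)
    ny, nx, nz = config.grid_shape
    fov = config.field_of_view
    dx, dy, dz = config.voxel
    bounds = (0.0, fov[0] - dx, 0.0, fov[1] - dy)
    step = max(min(dx, dy), 5.0)

    n_sup, n_deep = config.vessel_counts
    centerlines: list[dict] = []
    for _ in range(n_sup):
        start = rng.uniform([0, 0], [fov[0], fov[1]])
        heading = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(500.0, 1500.0)
        xy = _random_walk_polyline(
            rng, start, heading, length, step, config.capillary_tortuosity, bounds
        )
        diam = rng.uniform(*config.superficial_diam_range)
        clearance = rng.uniform(25.0, 60.0)
        zs = evaluate_surface(config.surface_coeffs, xy[:, 0], xy[:, 1], fov) - clearance
        zs = np.clip(zs, diam / 2 + dz, None)
        pts = np.column_stack([xy, zs])
        if len(pts) >= 2:
            centerlines.append(
                {"points": pts, "radii": np.full(len(pts), diam / 2.0), "layer": "superficial"}
            )
    for _ in range(n_deep):
        start = rng.uniform([0, 0], [fov[0], fov[1]])
        heading = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(2000.0, 6000.0)
        xy = _random_walk_polyline(rng, start, heading, length, step * 4, 0.05, bounds)
        diam = rng.uniform(*config.deep_diam_range)
        depth_below = rng.uniform(80.0, 250.0)
        zs = evaluate_surface(config.surface_coeffs, xy[:, 0], xy[:, 1], fov) + depth_below
        zs = np.clip(zs, None, config.depth - diam / 2 - dz)
        pts = np.column_stack([xy, zs])
        if len(pts) >= 2:
            centerlines.append(
                {"points": pts, "radii": np.full(len(pts), diam / 2.0), "layer": "deep"}
            )

    sup = np.zeros((ny, nx, nz), dtype=np.float32)
    deep = np.zeros((ny, nx, nz), dtype=np.float32)
    for cl in centerlines:
        target = sup if cl["layer"] == "superficial" else deep
        _render_polyline(target, cl["points"], cl["radii"], config.voxel)
    data = np.maximum(sup, deep)
    sup_mask = sup >= INSIDE_AMPLITUDE
    deep_mask = deep >= INSIDE_AMPLITUDE
    del sup, deep

    if config.psf_fwhm is not None:
        lat, ax = config.psf_fwhm
        s = (lat / 2.355 / dy, lat / 2.355 / dx, ax / 2.355 / dz)
        data = gaussian_filter(data, sigma=s)
    if config.noise_sigma > 0:
        data = data + rng.normal(0.0, config.noise_sigma, data.shape).astype(np.float32)

    xg = np.arange(nx) * dx
    yg = np.arange(ny) * dy
    surface = evaluate_surface(
        config.surface_coeffs,
        np.broadcast_to(xg[None, :], (ny, nx)),
        np.broadcast_to(yg[:, None], (ny, nx)),
        fov,
    )

    truth = GroundTruth(
        centerlines=centerlines,
        true_surface=surface,
        wound_mask=None,
        wound_center=None,
        metrics=_true_metrics(centerlines, None),
        superficial_mask=sup_mask,
        deep_mask=deep_mask,
    )
    vol = Volume(data, config.voxel, meta={"seed": config.seed, "kind": "two_layer_phantom"})
    return vol, truth


# ---------------------------------------------------------------------------
# wound time series


def _deviation_halfwidth(target_alignment: float) -> float:
    """Half-width a of Uniform(−a, a) orientation deviation with
    E[cos 2δ] = sin(2a)/(2a) equal to the target mean alignment."""
    t = float(np.clip(target_alignment, 0.0, 1.0))
    if t >= 0.999:
        return 0.0
    if t <= 1e-6:
        return math.pi / 2.0  # sin(π)/π = 0: exactly isotropic over ±90°

    def f(a: float) -> float:
        return math.sin(2 * a) / (2 * a) - t

    return brentq(f, 1e-6, math.pi / 2.0)


def make_wound_series(
    config: WoundSeriesConfig,
) -> list[tuple[Volume, GroundTruth]]:
    """Generate one healing wound as a time series of phantom volumes.

    Each timepoint contains (i) a background network outside the original
    wound, (ii) a ring of tortuous, dilated sprouts hugging the current
    avascular margin, and (iii) radially aligned vessels filling the
    re-vascularized annulus, with orientation scatter set by the
    alignment schedule and an in-wound turning rate that falls as
    alignment rises (sprouts mature: straighter and better aligned).
    """
    rng = np.random.default_rng(config.seed)
    fov = config.field_of_view
    center = (fov[0] / 2.0, fov[1] / 2.0)
    dxv, dyv, dzv = config.voxel
    nx = int(round(fov[0] / dxv))
    ny = int(round(fov[1] / dyv))
    nzv = int(round(config.depth / dzv))
    bounds = (0.0, fov[0] - dxv, 0.0, fov[1] - dyv)
    step = config.walk_step
    r0 = config.initial_radius

    out = []
    for t in config.timepoints:
        s = config.closure_score(t)
        r_w = config.wound_radius(t)
        align = config.alignment_at(t)
        # sprouts mature as the wound closes: straighter and better aligned
        ring_tortuosity = 1.3 - 0.8 * align
        radial_tortuosity = 0.05 + 0.5 * (1.0 - align)
        half = _deviation_halfwidth(align)
        centerlines: list[dict] = []

        def _depth_profile(n: int) -> np.ndarray:
            return np.full(n, float(rng.uniform(60.0, config.depth - 80.0)))

        def _clip_outside(xy: np.ndarray, radius: float) -> np.ndarray:
            rr = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
            return xy[rr > radius]

        # background network: jittered grid for uniform coverage to the borders
        pitch = config.background_spacing
        for gx in np.arange(pitch / 2, fov[0], pitch):
            for gy in np.arange(pitch / 2, fov[1], pitch):
                start = np.array([gx, gy]) + rng.uniform(-150, 150, 2)
                start = np.clip(start, [0, 0], [fov[0] - dxv, fov[1] - dyv])
                if math.hypot(start[0] - center[0], start[1] - center[1]) < r0 - 50:
                    continue
                xy = _random_walk_polyline(
                    rng, start, rng.uniform(0, 2 * math.pi),
                    rng.uniform(600, 1100), step, 0.5, bounds,
                )
                xy = _clip_outside(xy, r0)
                if len(xy) < 3:
                    continue
                diam = rng.uniform(10.0, 30.0)
                pts = np.column_stack([xy, _depth_profile(len(xy))])
                centerlines.append(
                    {"points": pts, "radii": np.full(len(pts), diam / 2), "layer": "background"}
                )

        # sprout ring hugging the current avascular margin from outside
        # (tortuous and dilated, the early-healing signature at the wound edge)
        if r_w > 150.0:
            for _ in range(config.ring_vessels):
                phi = rng.uniform(0, 2 * math.pi)
                # square-law bias toward the inner edge: sprouts hug the margin
                rad = r_w + rng.uniform(0.0, 1.0) ** 2 * config.sprout_ring_width
                start = np.array(
                    [center[0] + rad * math.cos(phi), center[1] + rad * math.sin(phi)]
                )
                heading = phi + math.pi / 2 + rng.uniform(-0.5, 0.5)
                xy = _random_walk_polyline(
                    rng, start, heading, rng.uniform(250, 450), step,
                    ring_tortuosity, bounds,
                )
                xy = _clip_outside(xy, r_w)
                if len(xy) < 3:
                    continue
                diam = rng.uniform(25.0, 40.0)
                pts = np.column_stack([xy, _depth_profile(len(xy))])
                centerlines.append(
                    {"points": pts, "radii": np.full(len(pts), diam / 2), "layer": "ring"}
                )

        # radially aligned vessels filling the re-vascularized annulus on a
        # jittered polar lattice (deterministic coverage up to the margin)
        if r_w < r0 - 100.0:
            pitch_r = config.radial_spacing
            for rad0 in np.arange(r_w + 60.0, r0, pitch_r):
                # angular pitch set mid-vessel so outward-fanning spokes stay
                # within closing range of each other along their whole length
                rad_mid = rad0 + 200.0
                n_phi = max(6, int(round(2 * math.pi * rad_mid / pitch_r)))
                for j in range(n_phi):
                    phi = 2 * math.pi * j / n_phi + rng.uniform(-0.3, 0.3) / max(rad0 / pitch_r, 1)
                    rad = rad0 + rng.uniform(-0.3, 0.3) * pitch_r
                    start = np.array(
                        [center[0] + rad * math.cos(phi), center[1] + rad * math.sin(phi)]
                    )
                    delta = rng.uniform(-half, half) if half > 0 else 0.0
                    heading = phi + delta  # radial direction plus scheduled deviation
                    max_len = min(450.0, (r0 - r_w) * 0.9)
                    xy = _random_walk_polyline(
                        rng, start, heading, rng.uniform(0.6 * max_len, max_len), step,
                        radial_tortuosity, bounds,
                    )
                    xy = _clip_outside(xy, r_w + 10.0)
                    if len(xy) < 3:
                        continue
                    diam = rng.uniform(10.0, 25.0)
                    pts = np.column_stack([xy, _depth_profile(len(xy))])
                    centerlines.append(
                        {"points": pts, "radii": np.full(len(pts), diam / 2), "layer": "radial"}
                    )

        data = np.zeros((ny, nx, nzv), dtype=np.float32)
        for cl in centerlines:
            _render_polyline(data, cl["points"], cl["radii"], config.voxel)
        if config.noise_sigma > 0:
            data = data + rng.normal(0.0, config.noise_sigma, data.shape).astype(np.float32)

        xg = np.arange(nx) * dxv
        yg = np.arange(ny) * dyv
        rgrid = np.hypot(xg[None, :] - center[0], yg[:, None] - center[1])
        # simply connected avascular disk; below one voxel the wound is closed
        if r_w >= min(dxv, dyv):
            wound_mask = rgrid < r_w
        else:
            wound_mask = np.zeros((ny, nx), dtype=bool)

        truth = GroundTruth(
            centerlines=centerlines,
            true_surface=None,
            wound_mask=wound_mask,
            wound_center=center,
            metrics=_true_metrics(centerlines, center),
        )
        truth.metrics["dpw"] = t
        truth.metrics["closure_score"] = s
        vol = Volume(
            data,
            config.voxel,
            meta={"seed": config.seed, "dpw": t, "kind": "wound_phantom",
                  "wound_radius_um": r_w, "initial_radius_um": r0},
        )
        out.append((vol, truth))
    return out


def make_tube_grid(
    diameters_um,
    lengths_um,
    voxel: tuple[float, float, float] = (5.0, 5.0, 5.0),
    spacing_um: float = 250.0,
    depth_um: float = 200.0,
    tube_depth_um: float = 100.0,
    noise_sigma: float = 0.02,
    tortuosity: float = 0.0,
    seed: int = 0,
) -> tuple[Volume, GroundTruth]:
    """A calibration scene: well-separated straight-ish tubes on a grid.

    One tube per (diameter, length) pair, laid out in rows ``spacing_um``
    apart at a common depth.  Used to validate diameter/length recovery
    of the measurement chain against known ground truth.
    """
    diameters = np.atleast_1d(np.asarray(diameters_um, dtype=float))
    lengths = np.atleast_1d(np.asarray(lengths_um, dtype=float))
    if len(lengths) == 1:
        lengths = np.full(len(diameters), lengths[0])
    if len(diameters) != len(lengths):
        raise ValueError("diameters and lengths must align")
    rng = np.random.default_rng(seed)
    dx, dy, dz = voxel
    margin = 150.0
    fov_x = float(lengths.max()) + 2 * margin
    fov_y = spacing_um * len(diameters) + margin
    nx = int(round(fov_x / dx))
    ny = int(round(fov_y / dy))
    nz = int(round(depth_um / dz))
    data = np.zeros((ny, nx, nz), dtype=np.float32)
    centerlines = []
    step = max(min(dx, dy), 5.0)
    for i, (d, L) in enumerate(zip(diameters, lengths)):
        y0 = margin / 2 + i * spacing_um
        if tortuosity > 0:
            xy = _random_walk_polyline(
                rng, np.array([margin, y0]), 0.0, L, step, tortuosity,
                (0.0, fov_x - dx, 0.0, fov_y - dy),
            )
        else:
            n = max(2, int(round(L / step)) + 1)
            xy = np.column_stack([np.linspace(margin, margin + L, n), np.full(n, y0)])
        pts = np.column_stack([xy, np.full(len(xy), tube_depth_um)])
        radii = np.full(len(pts), d / 2.0)
        _render_polyline(data, pts, radii, voxel)
        centerlines.append({"points": pts, "radii": radii, "layer": "tube"})
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, data.shape).astype(np.float32)
    truth = GroundTruth(
        centerlines=centerlines,
        true_surface=None,
        wound_mask=None,
        wound_center=None,
        metrics=_true_metrics(centerlines, None),
    )
    return Volume(data, voxel, meta={"kind": "tube_grid", "seed": seed}), truth


# ---------------------------------------------------------------------------
# edge target and raw scan streams


def make_edge_target(
    k: float,
    x0: float,
    step: float,
    noise_sigma: float = 0.0,
    half_width: float | None = None,
    seed: int = 0,
):
    """Synthesize an edge-spread scan y(x) = 1/(1+e^{−k(x−x0)}) + noise."""
    from .resolution import EdgeScan  # local import to avoid a cycle

    if k <= 0 or step <= 0:
        raise ValueError("k and step must be positive")
    if half_width is None:
        half_width = 8.0 / k
    n = int(math.floor(half_width / step))
    x = x0 + np.arange(-n, n + 1) * step  # grid centered on the edge
    y = 1.0 / (1.0 + np.exp(-k * (x - x0)))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, y.shape)
    return EdgeScan(x=x, y=y)


def make_raw_scan(
    volume: Volume,
    energy_jitter: float = 0.0,
    trajectory: str = "raster",
    seed: int = 0,
    oversample: float = 3.3,
) -> RawScan:
    """Serialize a volume into a per-pulse A-scan stream.

    Each pulse carries the volume's depth column at the pulse position
    (nearest lateral voxel), scaled by a per-pulse energy drawn uniformly
    in 1 ± ``energy_jitter``.  ``raster`` visits every column once in
    scan order; ``sinusoidal`` emulates the fast-axis voice-coil motion
    x(t) ∝ 1 − cos(ωt) against a slow linear y drive, with ``oversample``
    pulses per column-crossing so that every grid column is hit.
    """
    if not 0.0 <= energy_jitter < 1.0:
        raise ValueError("energy_jitter must be in [0, 1)")
    ny, nx, nz = volume.shape
    dx, dy, dz = volume.voxel
    rng = np.random.default_rng(seed)

    if trajectory == "raster":
        iy, ix = np.mgrid[0:ny, 0:nx]
        ix = ix.ravel()
        iy = iy.ravel()
        pos = np.column_stack([ix * dx, iy * dy]).astype(float)
    elif trajectory == "sinusoidal":
        per_period = int(math.ceil(math.pi * nx * oversample / 2.0))
        n_periods = ny + 1
        n = per_period * n_periods
        tt = np.arange(n) / per_period  # one x period per unit
        x = 0.5 * (nx - 1) * dx * (1.0 - np.cos(2 * math.pi * tt))
        y = (ny - 1) * dy * np.linspace(0.0, 1.0, n)
        pos = np.column_stack([x, y])
        ix = np.clip(np.round(x / dx).astype(int), 0, nx - 1)
        iy = np.clip(np.round(y / dy).astype(int), 0, ny - 1)
    else:
        raise ValueError(f"unknown trajectory {trajectory!r}")

    energies = (
        rng.uniform(1.0 - energy_jitter, 1.0 + energy_jitter, len(pos))
        if energy_jitter > 0
        else np.ones(len(pos))
    )
    ascans = volume.data[iy, ix, :] * energies[:, None].astype(volume.data.dtype)
    return RawScan(
        ascans=ascans, positions=pos, energies=energies, sample_rate=250e6, dz=dz
    )
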