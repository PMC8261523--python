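"""Wound-level aggregation: centers, scores, kinetics, maps, statistics.

* the wound center is the centroid of the largest non-vascularized
  connected component of a vascularized-area mask;
* the healing score is the healed fraction of the initial wound area,
  the vascularization score the re-vascularized fraction of the original
  wound area, both in [0, 1];
* closure dynamics are summarized by a logistic fit over days post
  wounding; the healing/vascularization *rate* is the normalized
  gradient of the fit, peaking at the midpoint t0;
* vessel metrics are pooled across wounds relative to each wound's
  center into 400 µm × 400 µm heat-map bins (6 mm extent) and into
  radial annuli;
* superficial vs deep calibre difference is assessed with a two-sample
  Student's t-test on per-wound median diameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "HealingCurve",
    "HeatMap",
    "wound_center",
    "healing_score",
    "vascularization_score",
    "vascularized_mask",
    "fit_healing_curve",
    "make_heatmaps",
    "radial_profiles",
    "compare_layer_diameters",
]

HEATMAP_METRICS = ("length_um", "diameter_um", "tortuosity_deg_per_um", "alignment")


@dataclass
class HealingCurve:
    """Logistic closure kinetics of one wound."""

    times: np.ndarray  # dpw
    scores: np.ndarray  # measured ratios in [0, 1]
    k: float  # day⁻¹
    t0: float  # day
    rate_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    rate_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_rate_time: float = 0.0
    residual: float = 0.0

    def fitted(self, t: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.k * (np.asarray(t, float) - self.t0)))


@dataclass
class HeatMap:
    """Per-metric 2D bins of vessel parameters around the wound center."""

    grids: dict[str, np.ndarray]  # metric -> (nb, nb) means, NaN where empty
    counts: np.ndarray  # (nb, nb) vessels per bin
    bin_um: float = 400.0
    extent_um: float = 6000.0

    def edges(self) -> np.ndarray:
        half = self.extent_um / 2
        return np.arange(-half, half + self.bin_um / 2, self.bin_um)


def wound_center(
    vasc_mask: np.ndarray, pixel: tuple[float, float] = (1.0, 1.0)
) -> tuple[float, float]:
    """Centroid (x, y in µm) of the largest non-vascularized component.

    Components touching the image border are ignored when any interior
    component exists: the wound sits inside the imaged field, whereas
    border-touching gaps are artifacts of finite coverage.
    """
    nonvasc = ~np.asarray(vasc_mask, dtype=bool)
    if not nonvasc.any():
        raise ValueError("no wound region: mask is fully vascularized")
    lab, n = ndimage.label(nonvasc)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    interior = np.ones(n, dtype=bool)
    interior[border[border > 0] - 1] = False
    if interior.any():
        sizes = np.where(interior, sizes, 0)
    biggest = int(np.argmax(sizes)) + 1
    cy, cx = ndimage.center_of_mass(lab == biggest)
    return (float(cx * pixel[0]), float(cy * pixel[1]))


def track_wound_center(
    vasc_mask: np.ndarray,
    pixel: tuple[float, float],
    prev_center: tuple[float, float],
    max_shift_um: float,
    min_area_um2: float,
) -> tuple[float, float]:
    """Re-locate a known wound in a later timepoint's mask.

    Wounds do not move between imaging sessions, so the avascular wound
    component is searched within ``max_shift_um`` of the previous center;
    the largest such component wins.  If none at least ``min_area_um2``
    remains (the wound has closed beyond detectability), the previous
    center is kept.
    """
    nonvasc = ~np.asarray(vasc_mask, dtype=bool)
    lab, n = ndimage.label(nonvasc)
    if n == 0:
        return prev_center
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=idx)
    cents = ndimage.center_of_mass(nonvasc, lab, index=idx)
    px_area = pixel[0] * pixel[1]
    best, best_size = None, 0.0
    for (cy, cx), size in zip(cents, sizes):
        area = size * px_area
        d = math.hypot(cx * pixel[0] - prev_center[0], cy * pixel[1] - prev_center[1])
        if d <= max_shift_um and area >= min_area_um2 and area > best_size:
            best, best_size = (float(cx * pixel[0]), float(cy * pixel[1])), area
    if best is None:
        logger.info("wound closed beyond detectability; keeping previous center")
        return prev_center
    return best


def healing_score(initial_area: float, current_wound_area: float) -> float:
    """Healed fraction of the initial wound area, clipped to [0, 1]."""
    if initial_area <= 0:
        raise ValueError("initial_area must be positive")
    if current_wound_area > 1.05 * initial_area:
        logger.warning("wound expanded beyond its initial area; score clipped to 0")
    return float(np.clip((initial_area - current_wound_area) / initial_area, 0.0, 1.0))


def vascularization_score(initial_area: float, revascularized_area: float) -> float:
    """Re-vascularized fraction of the original wound area, in [0, 1]."""
    if initial_area <= 0:
        raise ValueError("initial_area must be positive")
    if revascularized_area > 1.05 * initial_area:
        logger.warning("re-vascularized area exceeds initial wound area; clipped")
    return float(np.clip(revascularized_area / initial_area, 0.0, 1.0))


def vascularized_mask(
    vessel_mask: np.ndarray,
    pixel: tuple[float, float],
    closing_radius_um: float = 200.0,
    max_hole_diameter_um: float = 400.0,
) -> np.ndarray:
    """Vascularized-area mask from a binary vessel mask.

    Morphological closing with a disk bridges gaps between neighbouring
    vessels; only holes smaller than ``max_hole_diameter_um`` are then
    filled, so that a genuinely avascular wound core enclosed by a sprout
    ring is preserved rather than erased.  The disk closing is realized
    with two Euclidean distance transforms (exact for disk structuring
    elements, and fast for physically large radii).
    """
    mask = np.asarray(vessel_mask, bool)
    if not mask.any():
        return mask.copy()
    sampling = (pixel[1], pixel[0])
    dilated = ndimage.distance_transform_edt(~mask, sampling=sampling) <= closing_radius_um
    closed = ndimage.distance_transform_edt(dilated, sampling=sampling) > closing_radius_um
    closed |= mask  # erosion at the image border must not eat real vessels
    # fill enclosed holes below the size cutoff
    holes, n = ndimage.label(~closed)
    if n:
        border = np.unique(
            np.concatenate([holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]])
        )
        sizes = ndimage.sum_labels(np.ones_like(holes), holes, index=np.arange(1, n + 1))
        px_area = pixel[0] * pixel[1]
        cutoff = math.pi * (max_hole_diameter_um / 2) ** 2 / px_area
        fill = [
            i + 1
            for i in range(n)
            if sizes[i] < cutoff and (i + 1) not in border
        ]
        if fill:
            closed[np.isin(holes, fill)] = True
    return closed


def _logistic(t: np.ndarray, k: float, t0: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * (t - t0)))


def fit_healing_curve(times, scores, n_rate: int = 200) -> HealingCurve:
    """Least-squares logistic fit of closure/vascularization scores.

    The rate curve is the time derivative of the fit normalized to unit
    maximum; by the symmetry of the logistic its peak sits at t0.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 timepoints")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if np.ptp(s) < 1e-9:
        raise ValueError("degenerate input: scores carry no closure signal")

    t0_init = float(np.interp(0.5, s, t)) if np.all(np.diff(s) >= 0) else float(np.mean(t))
    sol = least_squares(
        lambda p: _logistic(t, p[0], p[1]) - s,
        x0=[1.0, t0_init],
        bounds=([1e-6, t.min() - 50], [100.0, t.max() + 50]),
        xtol=1e-15,
        ftol=1e-15,
    )
    if not sol.success:
        raise RuntimeError(f"logistic fit did not converge: residual {sol.cost:.3g}")
    k, t0 = float(sol.x[0]), float(sol.x[1])
    tt = np.linspace(t.min(), t.max(), n_rate)
    rate = np.gradient(_logistic(tt, k, t0), tt)
    peak = rate.max()
    rate = rate / peak if peak > 0 else rate
    return HealingCurve(
        times=t,
        scores=s,
        k=k,
        t0=t0,
        rate_times=tt,
        rate_curve=rate,
        peak_rate_time=t0,
        residual=float(np.sum(sol.fun**2)),
    )


def _relative_positions(
    tables: list[pd.DataFrame], centers: list[tuple[float, float]]
) -> pd.DataFrame:
    if len(tables) == 0 or len(tables) != len(centers):
        raise ValueError("need one wound center per vessel table")
    parts = []
    for tab, c in zip(tables, centers):
        t = tab.copy()
        t["rel_x_um"] = t["midpoint_x_um"] - c[0]
        t["rel_y_um"] = t["midpoint_y_um"] - c[1]
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def make_heatmaps(
    tables: list[pd.DataFrame],
    centers: list[tuple[float, float]],
    bin_um: float = 400.0,
    extent_um: float = 6000.0,
    metrics: tuple[str, ...] = HEATMAP_METRICS,
) -> HeatMap:
    """Pool vessels across wounds into wound-centered square bins.

    Each bin holds the mean of the member vessels' metric; empty bins are
    NaN, never zero.  Vessels are pooled first and binned second, so
    wounds with more vessels weigh more.
    """
    pooled = _relative_positions(tables, centers)
    half = extent_um / 2
    nb = int(round(extent_um / bin_um))
    edges = np.linspace(-half, half, nb + 1)
    inside = (
        (pooled["rel_x_um"] >= -half)
        & (pooled["rel_x_um"] < half)
        & (pooled["rel_y_um"] >= -half)
        & (pooled["rel_y_um"] < half)
    )
    sub = pooled[inside]
    bx = np.clip(np.digitize(sub["rel_x_um"], edges) - 1, 0, nb - 1)
    by = np.clip(np.digitize(sub["rel_y_um"], edges) - 1, 0, nb - 1)
    counts = np.zeros((nb, nb), dtype=int)
    np.add.at(counts, (by, bx), 1)
    grids: dict[str, np.ndarray] = {}
    for m in metrics:
        if m not in sub.columns:
            continue
        acc = np.zeros((nb, nb))
        np.add.at(acc, (by, bx), np.nan_to_num(sub[m].to_numpy(float)))
        with np.errstate(invalid="ignore"):
            grids[m] = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    return HeatMap(grids=grids, counts=counts, bin_um=bin_um, extent_um=extent_um)


def radial_profiles(
    tables: list[pd.DataFrame],
    centers: list[tuple[float, float]],
    bin_width: float = 250.0,
    max_radius: float | None = None,
    metrics: tuple[str, ...] = HEATMAP_METRICS,
) -> pd.DataFrame:
    """Mean vessel metrics per annulus of distance from the wound center.

    Returns one row per (dpw, annulus) with per-metric means and the
    vessel count ``n``; annuli without vessels are absent (missing, not
    zero).  Vessels are pooled across wounds within each dpw.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pooled = _relative_positions(tables, centers)
    pooled["r_um"] = np.hypot(pooled["rel_x_um"], pooled["rel_y_um"])
    if max_radius is None:
        max_radius = float(pooled["r_um"].max()) + bin_width
    pooled = pooled[pooled["r_um"] < max_radius]
    pooled["annulus"] = (pooled["r_um"] // bin_width).astype(int)
    if "dpw" not in pooled.columns:
        pooled["dpw"] = np.nan
    avail = [m for m in metrics if m in pooled.columns]
    g = pooled.groupby(["dpw", "annulus"], dropna=False)
    out = g[avail].mean()
    out["n"] = g.size()
    out = out.reset_index()
    out["r_inner_um"] = out["annulus"] * bin_width
    out["r_outer_um"] = (out["annulus"] + 1) * bin_width
    out["r_mid_um"] = out["r_inner_um"] + bin_width / 2
    return out.drop(columns=["annulus"])


def compare_layer_diameters(
    superficial_medians,
    deep_medians,
    equal_var: bool = True,
) -> dict:
    """Student's t-test on per-wound median diameters, with group CIs.

    Returns t, the two-sided p-value, group means, and normal-theory 95%
    confidence intervals.  ``equal_var=False`` switches to the Welch
    variant.
    """
    a = np.asarray(superficial_medians, dtype=float)
    b = np.asarray(deep_medians, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 wounds per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate zero-variance groups: t is 0 (equal means) or ±inf
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)

    def ci(x):
        m = x.mean()
        sem = x.std(ddof=1) / math.sqrt(len(x))
        h = stats.t.ppf(0.975, len(x) - 1) * sem
        return (m - h, m + h)

    return {
        "t": float(t),
        "p": float(p),
        "mean_superficial": float(a.mean()),
        "mean_deep": float(b.mean()),
        "ci_superficial": ci(a),
        "ci_deep": ci(b),
        "n": (len(a), len(b)),
    }
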