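"""Wound centers, scores, kinetics, heat maps, profiles and statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from woundvasc.wound import (
    compare_layer_diameters,
    fit_healing_curve,
    healing_score,
    make_heatmaps,
    radial_profiles,
    vascularization_score,
    wound_center,
)


class TestWoundCenter:
    def test_disk_centroid(self):
        mask = np.ones((200, 200), dtype=bool)
        yy, xx = np.mgrid[0:200, 0:200]
        mask[(xx - 120) ** 2 + (yy - 80) ** 2 < 30**2] = False
        cx, cy = wound_center(mask, pixel=(10.0, 10.0))
        assert cx == pytest.approx(1200.0, abs=10.0)
        assert cy == pytest.approx(800.0, abs=10.0)

    def test_largest_component_wins(self):
        mask = np.ones((200, 200), dtype=bool)
        yy, xx = np.mgrid[0:200, 0:200]
        mask[(xx - 60) ** 2 + (yy - 60) ** 2 < 40**2] = False
        mask[(xx - 150) ** 2 + (yy - 150) ** 2 < 12**2] = False
        cx, cy = wound_center(mask, pixel=(1.0, 1.0))
        assert math.hypot(cx - 60, cy - 60) < 2.0

    def test_fully_vascularized_rejected(self):
        with pytest.raises(ValueError, match="no wound region"):
            wound_center(np.ones((10, 10), dtype=bool))

    def test_phantom_series_centers(self, wound_series_default):
        """Measured center within 100 µm of ground truth at each dpw."""
        from woundvasc.config import RunConfig
        from woundvasc.pipeline import analyze_timepoint

        cfg, series = wound_series_default
        rc = RunConfig()
        centers = []
        for (vol, truth), t in zip(series, cfg.timepoints):
            res = analyze_timepoint(
                vol, rc, t, fallback_center=centers[0] if centers else None
            )
            centers.append(res["center"])
            err = math.hypot(
                res["center"][0] - truth.wound_center[0],
                res["center"][1] - truth.wound_center[1],
            )
            assert err < 100.0


class TestScores:
    def test_healing_arithmetic(self):
        assert healing_score(100.0, 100.0) == 0.0
        assert healing_score(100.0, 0.0) == 1.0
        assert healing_score(100.0, 25.0) == 0.75

    def test_vascularization_bounds(self):
        assert vascularization_score(100.0, 0.0) == 0.0
        assert vascularization_score(100.0, 100.0) == 1.0
        assert vascularization_score(100.0, 130.0) == 1.0  # clipped

    def test_invalid_initial_area(self):
        with pytest.raises(ValueError):
            healing_score(0.0, 10.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        initial=st.floats(1e-3, 1e9),
        current=st.floats(0, 2e9),
    )
    def test_scores_always_in_unit_interval(self, initial, current):
        assert 0.0 <= healing_score(initial, current) <= 1.0
        assert 0.0 <= vascularization_score(initial, current) <= 1.0


class TestHealingCurve:
    def test_exact_logistic_recovered(self):
        t = np.array([3.0, 5.0, 6.0, 7.0, 9.0, 12.0])
        s = 1 / (1 + np.exp(-1.2 * (t - 5.5)))
        curve = fit_healing_curve(t, s)
        assert curve.k == pytest.approx(1.2, abs=1e-6)
        assert curve.t0 == pytest.approx(5.5, abs=1e-6)
        assert curve.peak_rate_time == pytest.approx(5.5, abs=1e-6)
        assert curve.rate_curve.max() == pytest.approx(1.0)

    def test_noisy_recovery_over_seeds(self):
        t = np.array([3.0, 5.0, 6.0, 7.0, 9.0, 12.0])
        s = 1 / (1 + np.exp(-1.2 * (t - 5.5)))
        rng = np.random.default_rng(1)
        errs = [
            abs(fit_healing_curve(t, np.clip(s + rng.normal(0, 0.03, 6), 0, 1)).t0 - 5.5)
            for _ in range(100)
        ]
        assert np.median(errs) < 0.5

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_healing_curve([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            fit_healing_curve([1.0, 2.0, 3.0], [0.1, 0.5, 0.9])


def _table(positions, **metrics):
    n = len(positions)
    base = {
        "midpoint_x_um": [p[0] for p in positions],
        "midpoint_y_um": [p[1] for p in positions],
        "length_um": np.full(n, 100.0),
        "diameter_um": np.full(n, 20.0),
        "tortuosity_deg_per_um": np.full(n, 0.5),
        "alignment": np.full(n, 0.0),
        "dpw": np.full(n, 5.0),
    }
    base.update(metrics)
    return pd.DataFrame(base)


class TestHeatmaps:
    def test_single_vessel_occupies_one_bin(self):
        tab = _table([(500.0, 500.0)])
        hm = make_heatmaps([tab], [(0.0, 0.0)])
        assert hm.counts.sum() == 1
        by, bx = np.argwhere(hm.counts == 1)[0]
        # bin edges at -3000 .. 3000 step 400: +500 lands in bin index 8
        assert (bx, by) == (8, 8)

    def test_translation_invariance(self):
        tab1 = _table([(500.0, -300.0), (1000.0, 900.0)])
        shift = (12345.0, -678.0)
        tab2 = tab1.copy()
        tab2["midpoint_x_um"] += shift[0]
        tab2["midpoint_y_um"] += shift[1]
        h1 = make_heatmaps([tab1], [(0.0, 0.0)])
        h2 = make_heatmaps([tab2], [shift])
        assert np.array_equal(h1.counts, h2.counts)
        for k in h1.grids:
            assert np.allclose(h1.grids[k], h2.grids[k], equal_nan=True)

    def test_count_conservation_inside_extent(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-4000, 4000, (200, 2))
        tab = _table([tuple(p) for p in pos])
        hm = make_heatmaps([tab], [(0.0, 0.0)])
        inside = np.sum(np.all(np.abs(pos) < 3000.0, axis=1))
        assert hm.counts.sum() == inside

    def test_empty_bins_are_nan(self):
        hm = make_heatmaps([_table([(500.0, 500.0)])], [(0.0, 0.0)])
        g = hm.grids["diameter_um"]
        assert np.isnan(g[0, 0])
        assert np.isfinite(g[8, 8])


class TestRadialProfiles:
    def test_uniform_table_flat_profile(self):
        rng = np.random.default_rng(2)
        r = np.sqrt(rng.uniform(0, 1, 3000)) * 2500.0
        phi = rng.uniform(0, 2 * np.pi, 3000)
        tab = _table(list(zip(r * np.cos(phi), r * np.sin(phi))))
        prof = radial_profiles([tab], [(0.0, 0.0)], bin_width=500.0)
        vals = prof[prof["n"] > 30]["diameter_um"]
        assert vals.std() < 0.5  # constant metric stays flat

    def test_empty_annuli_absent_not_zero(self):
        tab = _table([(100.0, 0.0), (2600.0, 0.0)])
        prof = radial_profiles([tab], [(0.0, 0.0)], bin_width=250.0)
        assert set(prof["r_inner_um"]) == {0.0, 2500.0}
        assert (prof["n"] > 0).all()


class TestLayerComparison:
    def test_identical_groups(self):
        res = compare_layer_diameters([16.0, 16.0, 16.0], [16.0, 16.0, 16.0])
        assert res["t"] == 0.0
        assert res["p"] == 1.0

    def test_hand_computed_three_vs_three(self):
        a, b = [15.0, 16.0, 17.0], [40.0, 43.0, 46.0]
        res = compare_layer_diameters(a, b)
        # pooled-variance Student's t with n1=n2=3
        sa2, sb2 = np.var(a, ddof=1), np.var(b, ddof=1)
        sp = math.sqrt(((sa2 + sb2) / 2) * (2 / 3))
        t_manual = (np.mean(a) - np.mean(b)) / sp
        assert res["t"] == pytest.approx(t_manual, rel=1e-12)
        assert res["p"] == pytest.approx(
            2 * stats.t.sf(abs(t_manual), 4), rel=1e-12
        )

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(16.0, 1.0, 28)
        b = rng.normal(43.0, 5.0, 28)
        res = compare_layer_diameters(a, b)
        assert res["p"] < 1e-20
        assert res["mean_superficial"] < res["mean_deep"]
        lo, hi = res["ci_superficial"]
        assert lo < 16.0 < hi

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            compare_layer_diameters([16.0], [40.0, 42.0])
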