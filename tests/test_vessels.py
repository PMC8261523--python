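"""Binarization, skeleton branch decomposition and morphometrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from woundvasc.layers import multiscale_vesselness
from woundvasc.phantom import make_tube_grid
from woundvasc.preprocess import max_amplitude_projection
from woundvasc.vessels import (
    VesselSegment,
    alignment_scores,
    angular_alignment,
    binarize_vessels,
    chord_angle,
    measure_map,
    measure_segment,
    polyline_tortuosity,
    skeletonize_and_segment,
    smooth_centerline,
)


class TestBinarize:
    def test_all_zero_gives_empty_mask(self):
        img = np.zeros((32, 32))
        assert not binarize_vessels(img, img).any()

    def test_tube_recovered_at_modest_snr(self):
        """SNR-10 projection: ≥95% of true tube pixels kept, ≤5% spurious."""
        clean, _ = make_tube_grid([30.0], [600.0], voxel=(5.0, 5.0, 5.0), noise_sigma=0.0)
        cm = max_amplitude_projection(clean).map
        rng = np.random.default_rng(1)
        noisy = cm + rng.normal(0.0, 0.1, cm.shape)
        vn = multiscale_vesselness(np.clip(noisy, 0, None) / noisy.max(), (15.0, 30.0), 5.0)
        mask = binarize_vessels(noisy, vn)
        true_px = cm >= math.exp(-2)
        recovered = (mask & true_px).sum() / true_px.sum()
        false_pos = (mask & ~true_px).sum() / max(mask.sum(), 1)
        assert recovered >= 0.95
        assert false_pos <= 0.05

    def test_raising_high_threshold_never_adds_pixels(self):
        vol, _ = make_tube_grid([30.0, 15.0], [500.0], noise_sigma=0.05, seed=2)
        proj = max_amplitude_projection(vol)
        vn = multiscale_vesselness(proj.map / proj.map.max(), (10.0, 20.0), 5.0)
        m_low = binarize_vessels(proj.map, vn, high=0.25)
        m_high = binarize_vessels(proj.map, vn, high=0.6)
        assert not (m_high & ~m_low).any()


class TestSkeleton:
    def test_single_tube_single_segment(self):
        mask = np.zeros((21, 60), dtype=bool)
        mask[9:12, 5:55] = True
        cls = skeletonize_and_segment(mask, min_length=10, pixel=(1.0, 1.0))
        assert len(cls) == 1

    def test_plus_crossing_four_segments(self):
        mask = np.zeros((61, 61), dtype=bool)
        mask[29:32, 5:56] = True
        mask[5:56, 29:32] = True
        cls = skeletonize_and_segment(mask, min_length=10, pixel=(1.0, 1.0))
        assert len(cls) == 4

    def test_well_separated_vessel_count(self, tube_grid_scene):
        """Segment count within 10% of the generated vessel count."""
        vol, truth = tube_grid_scene
        proj = max_amplitude_projection(vol)
        vn = multiscale_vesselness(proj.map / proj.map.max(), (10.0, 20.0, 40.0), 5.0)
        segs = measure_map(proj.map, vn, proj.pixel, min_length=30.0)
        n_true = len(truth.centerlines)
        assert abs(len(segs) - n_true) <= 0.1 * n_true


class TestMeasure:
    def test_straight_segment(self):
        n = 501
        cl = np.column_stack([np.linspace(0, 500, n), np.full(n, 50.0)])
        dist = np.full((200, 600), 10.0)
        seg = measure_segment(cl, dist, pixel=(1.0, 1.0))
        assert seg.length == pytest.approx(500.0)
        assert seg.tortuosity == 0.0

    def test_semicircle_tortuosity(self):
        r = 100.0
        th = np.linspace(0, math.pi, int(math.pi * r) + 1)
        cl = np.column_stack([150 + r * np.cos(th), 150 + r * np.sin(th)])
        dist = np.full((400, 400), 5.0)
        seg = measure_segment(cl, dist, pixel=(1.0, 1.0))
        assert seg.tortuosity == pytest.approx(0.573, abs=0.006)

    def test_two_point_centerline_tortuosity_zero(self):
        cl = np.array([[0.0, 0.0], [100.0, 0.0]])
        seg = measure_segment(cl, np.full((20, 20), 5.0), pixel=(10.0, 10.0))
        assert seg.tortuosity == 0.0

    def test_rendered_tube_diameter(self):
        """A radius-10 µm rendered tube measures 20 ± 2 µm."""
        vol, _ = make_tube_grid([20.0], [600.0], voxel=(5.0, 5.0, 5.0), noise_sigma=0.0)
        proj = max_amplitude_projection(vol)
        vn = multiscale_vesselness(proj.map / proj.map.max(), (10.0, 20.0), 5.0)
        segs = measure_map(proj.map, vn, proj.pixel, min_length=100.0)
        assert len(segs) == 1
        assert segs[0].diameter == pytest.approx(20.0, abs=2.0)

    def test_sampling_stability_of_arc_tortuosity(self):
        """Halving the centerline step changes the estimate by < 2%."""
        r = 150.0
        ths = [np.linspace(0, math.pi, n) for n in (236, 472)]  # 2 µm and 1 µm steps
        vals = []
        for th in ths:
            cl = np.column_stack([r * np.cos(th), r * np.sin(th)])
            vals.append(polyline_tortuosity(smooth_centerline(cl, 5)))
        assert abs(vals[0] - vals[1]) / vals[1] < 0.02


class TestAlignment:
    def test_radial_segment_scores_one(self):
        seg = VesselSegment(
            centerline=np.array([[100.0, 0.0], [200.0, 0.0]]),
            length=100, diameter=10, angle=0.0, tortuosity=0.0, midpoint=(150.0, 0.0),
        )
        assert angular_alignment(seg, (0.0, 0.0)) == pytest.approx(1.0)

    def test_circumferential_segment_scores_minus_one(self):
        seg = VesselSegment(
            centerline=np.array([[150.0, -50.0], [150.0, 50.0]]),
            length=100, diameter=10, angle=90.0, tortuosity=0.0, midpoint=(150.0, 0.0),
        )
        assert angular_alignment(seg, (0.0, 0.0)) == pytest.approx(-1.0)

    def test_midpoint_at_center_rejected(self):
        seg = VesselSegment(
            centerline=np.array([[0.0, 0.0], [1.0, 0.0]]),
            length=1, diameter=1, angle=0.0, tortuosity=0.0, midpoint=(0.0, 0.0),
        )
        with pytest.raises(ValueError):
            angular_alignment(seg, (0.0, 0.0))

    def test_isotropic_orientations_average_zero(self):
        rng = np.random.default_rng(0)
        n = 100_000
        angles = rng.uniform(0.0, 180.0, n)
        mid = rng.normal(0.0, 1000.0, (n, 2))
        scores = alignment_scores(angles, mid, (0.0, 0.0))
        assert abs(np.nanmean(scores)) < 0.01

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(angle=st.floats(0, 179.99), mx=st.floats(-1e3, 1e3), my=st.floats(-1e3, 1e3))
    def test_score_bounded(self, angle, mx, my):
        if mx == 0 and my == 0:
            return
        s = alignment_scores(np.array([angle]), np.array([[mx, my]]), (0.0, 0.0))[0]
        assert -1.0 <= s <= 1.0


def test_rotation_equivariance():
    """Rotating the scene and the wound center leaves metrics unchanged (≤3%)."""
    vol, _ = make_tube_grid(
        [24.0], [500.0], voxel=(5.0, 5.0, 5.0), noise_sigma=0.0, tortuosity=0.4, seed=3
    )
    proj = max_amplitude_projection(vol)

    def measure(map2d, center):
        vn = multiscale_vesselness(map2d / map2d.max(), (12.0, 24.0), 5.0)
        segs = measure_map(map2d, vn, (5.0, 5.0), min_length=100.0, wound_center=center)
        return max(segs, key=lambda s: s.length)

    ny, nx = proj.map.shape
    seg0 = measure(proj.map, (-1000.0, -1000.0))
    al0 = seg0.alignment

    map90 = np.rot90(proj.map)  # (y, x) -> (nx-1-x, y): center rotates alike
    c90 = (-1000.0, (nx - 1) * 5.0 + 1000.0)
    seg90 = measure(map90, c90)
    al90 = seg90.alignment
    assert seg90.length == pytest.approx(seg0.length, rel=0.03)
    assert seg90.diameter == pytest.approx(seg0.diameter, rel=0.03)
    assert seg90.tortuosity == pytest.approx(seg0.tortuosity, abs=0.05)
    assert al90 == pytest.approx(al0, abs=0.06)


def test_morphometry_parameter_recovery(tube_grid_scene):
    """Measured vs generated length and diameter correlate with r > 0.9."""
    vol, truth = tube_grid_scene
    proj = max_amplitude_projection(vol)
    vn = multiscale_vesselness(proj.map / proj.map.max(), (10.0, 20.0, 40.0), 5.0)
    segs = measure_map(proj.map, vn, proj.pixel, min_length=30.0)
    tm = truth.metrics
    pairs = []
    for s in segs:
        i = int(np.argmin(np.abs(tm["midpoint_y_um"].to_numpy() - s.midpoint[1])))
        pairs.append(
            (tm["length_um"][i], s.length, tm["diameter_um"][i], s.diameter)
        )
    tl, ml, td, md = map(np.array, zip(*pairs))
    assert np.corrcoef(tl, ml)[0, 1] > 0.9
    assert np.corrcoef(td, md)[0, 1] > 0.9
    assert np.median(np.abs(md - td) / td) < 0.15
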