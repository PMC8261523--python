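"""Filtering, energy correction, regridding, projection and rendering."""

import numpy as np
import pytest

from woundvasc.containers import RawScan, Volume
from woundvasc.phantom import PhantomConfig, make_raw_scan, make_vessel_phantom
from woundvasc.preprocess import (
    bandpass_filter,
    clahe,
    depth_encode,
    energy_correct,
    max_amplitude_projection,
    regrid,
)


def _scan(ascans):
    ascans = np.atleast_2d(ascans)
    n = ascans.shape[0]
    return RawScan(ascans, np.zeros((n, 2)), np.ones(n))


class TestBandpass:
    def test_dc_suppressed(self):
        out = bandpass_filter(_scan(np.ones(1024)))
        peak = np.abs(out.ascans).max()
        assert 20 * np.log10(max(peak, 1e-30)) < -40.0

    def test_passband_tone_preserved(self):
        t = np.arange(1024) / 250e6
        out = bandpass_filter(_scan(np.sin(2 * np.pi * 10e6 * t)))
        gain_db = 20 * np.log10(np.abs(out.ascans[0, 300:700]).max())
        assert abs(gain_db) < 1.0

    def test_stopband_tone_attenuated(self):
        t = np.arange(1024) / 250e6
        out = bandpass_filter(_scan(np.sin(2 * np.pi * 100e6 * t)))
        gain_db = 20 * np.log10(np.abs(out.ascans[0, 300:700]).max())
        assert gain_db < -15.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(1, 512))
        b = rng.normal(size=(1, 512))
        fa = bandpass_filter(_scan(a)).ascans
        fb = bandpass_filter(_scan(b)).ascans
        fab = bandpass_filter(_scan(2 * a + 3 * b)).ascans
        assert np.abs(fab - 2 * fa - 3 * fb).max() < 1e-9

    def test_cutoffs_validated(self):
        with pytest.raises(ValueError):
            bandpass_filter(_scan(np.ones(64)), low=2e6, high=200e6)


class TestEnergyCorrect:
    def test_unit_energies_identity(self):
        raw = _scan(np.arange(32, dtype=float))
        out = energy_correct(raw)
        assert np.array_equal(out.ascans, raw.ascans)

    def test_uniform_scaling_inverted(self):
        a = np.arange(32, dtype=float)[None, :]
        raw = RawScan(2.0 * a, np.zeros((1, 2)), np.array([2.0]))
        out = energy_correct(raw)
        assert np.allclose(out.ascans, a)
        assert np.allclose(out.energies, 1.0)

    def test_non_positive_energy_names_pulse(self):
        raw = RawScan(np.ones((3, 4)), np.zeros((3, 2)), np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="index 1"):
            energy_correct(raw)

    def test_jittered_phantom_round_trip(self):
        cfg = PhantomConfig(
            field_of_view=(300.0, 300.0), depth=100.0, voxel=(10.0, 10.0, 5.0),
            vessel_counts=(3, 1), noise_sigma=0.0, seed=5,
        )
        vol, _ = make_vessel_phantom(cfg)
        raw = make_raw_scan(vol, energy_jitter=0.2, trajectory="sinusoidal", seed=1)
        back = regrid(energy_correct(raw), (30, 30, 10.0, 10.0))
        err = np.abs(back.data - vol.data).max() / vol.data.max()
        assert err < 1e-6


class TestRegrid:
    def test_two_pulses_averaged(self):
        ascans = np.array([[2.0, 4.0], [4.0, 8.0], [1.0, 1.0]])
        positions = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
        raw = RawScan(ascans, positions, np.ones(3))
        out = regrid(raw, (2, 1, 10.0, 10.0))
        assert np.allclose(out.data[0, 0], [3.0, 6.0])
        assert np.allclose(out.data[0, 1], [1.0, 1.0])

    def test_empty_node_fraction_errors(self):
        raw = RawScan(np.ones((2, 3)), np.zeros((2, 2)), np.ones(2))
        with pytest.raises(ValueError, match="no pulse"):
            regrid(raw, (10, 10, 10.0, 10.0))

    def test_positions_outside_grid_rejected(self):
        raw = RawScan(np.ones((1, 3)), np.array([[500.0, 0.0]]), np.ones(1))
        with pytest.raises(ValueError, match="outside"):
            regrid(raw, (4, 4, 10.0, 10.0))


class TestProjection:
    def test_single_voxel(self):
        data = np.zeros((4, 5, 50), dtype=np.float32)
        data[2, 3, 37] = 0.7
        proj = max_amplitude_projection(Volume(data, (10, 10, 5)))
        assert proj.map[2, 3] == pytest.approx(0.7)
        assert proj.depth_index[2, 3] == 37
        assert proj.zero_depth == 37 * 5.0

    def test_tie_takes_first_maximum(self):
        data = np.ones((3, 3, 8), dtype=np.float32)
        proj = max_amplitude_projection(Volume(data, (10, 10, 5)))
        assert np.all(proj.depth_index == 0)

    def test_phantom_vessel_depths_recovered(self, two_layer_phantom):
        """Depth index lands within 2 voxels of true capillary depth."""
        cfg, (vol, truth) = two_layer_phantom
        proj = max_amplitude_projection(vol)
        dz = vol.voxel[2]
        errors = []
        for cl in truth.centerlines:
            if cl["layer"] != "superficial":
                continue
            pts = cl["points"][::5]
            cols = np.clip((pts[:, 0] / 10).round().astype(int), 0, vol.shape[1] - 1)
            rows = np.clip((pts[:, 1] / 10).round().astype(int), 0, vol.shape[0] - 1)
            est = proj.depth_index[rows, cols] * dz
            errors.extend(np.abs(est - pts[:, 2]))
        assert np.median(errors) < 2 * dz


class TestClahe:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.4)
        assert np.allclose(clahe(img), 0.4)

    def test_output_in_unit_range(self):
        rng = np.random.default_rng(0)
        img = rng.gamma(2.0, 5.0, (80, 80))
        out = clahe(img)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_contrast_not_reduced_on_bimodal(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 0.05
        img[10:20, 10:20] = 1.0
        out = clahe(img)
        assert out.std() / out.mean() >= img.std() / img.mean() * 0.9

    def test_oversized_tile_falls_back_to_global(self, caplog):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        out = clahe(img, tile_size=64)
        assert out.shape == img.shape and out.max() <= 1.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            clahe(np.array([[-1.0, 0.5]]))


class TestDepthEncode:
    def _proj(self, depth_index):
        m = np.ones_like(depth_index, dtype=float)
        from woundvasc.containers import Projection

        return Projection(m, depth_index, (10, 10), 5.0, 0.0)

    def test_flat_depth_single_hue(self):
        rgb = depth_encode(self._proj(np.full((8, 8), 3)))
        flat = rgb.reshape(-1, 3)
        assert np.allclose(flat, flat[0])

    def test_two_depths_two_hues(self):
        di = np.zeros((4, 4), dtype=int)
        di[:, 2:] = 20
        rgb = depth_encode(self._proj(di))
        assert not np.allclose(rgb[0, 0], rgb[0, 3])

    def test_deterministic(self, two_layer_phantom):
        _, (vol, _) = two_layer_phantom
        proj = max_amplitude_projection(vol)
        r1 = depth_encode(proj)
        r2 = depth_encode(proj)
        assert np.array_equal(r1, r2)


def test_full_chain_matches_direct_projection():
    """raw→volume→MAP on a clean phantom equals the direct MAP."""
    cfg = PhantomConfig(
        field_of_view=(300.0, 300.0), depth=100.0, voxel=(10.0, 10.0, 5.0),
        vessel_counts=(3, 1), noise_sigma=0.0, seed=9,
    )
    vol, _ = make_vessel_phantom(cfg)
    raw = make_raw_scan(vol, 0.0, "sinusoidal")
    back = regrid(energy_correct(raw), (30, 30, 10.0, 10.0))
    p1 = max_amplitude_projection(back)
    p2 = max_amplitude_projection(vol)
    assert np.allclose(p1.map, p2.map, atol=1e-6)
    assert np.array_equal(p1.depth_index, p2.depth_index)
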