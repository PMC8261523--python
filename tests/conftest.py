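"""Shared fixtures: phantoms are generated once per session where tests
can share them without loss of independence."""

from __future__ import annotations

import numpy as np
import pytest

from woundvasc.phantom import (
    PhantomConfig,
    WoundSeriesConfig,
    make_tube_grid,
    make_vessel_phantom,
    make_wound_series,
)


@pytest.fixture(scope="session")
def two_layer_phantom():
    """A mid-size two-layer scene with ground truth (3.5 × 3.5 mm²)."""
    cfg = PhantomConfig(
        field_of_view=(3500.0, 3500.0),
        depth=800.0,
        voxel=(10.0, 10.0, 5.0),
        vessel_counts=(20, 8),
        seed=1,
    )
    return cfg, make_vessel_phantom(cfg)


@pytest.fixture(scope="session")
def tube_grid_scene():
    """Straight calibration tubes, diameters spanning 10–50 µm at 5 µm pixels."""
    rng = np.random.default_rng(7)
    diameters = np.linspace(10.0, 50.0, 36)
    lengths = rng.uniform(300.0, 1200.0, 36)
    vol, truth = make_tube_grid(diameters, lengths, seed=7)
    return vol, truth


@pytest.fixture(scope="session")
def wound_series_default():
    """One simulated healing wound at the default study conditions."""
    cfg = WoundSeriesConfig(seed=3)
    return cfg, make_wound_series(cfg)
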