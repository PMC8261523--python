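"""Shared in-memory containers for volumes, projections and raw scan streams.

Conventions used throughout the package:

* indices ``(iy, ix, iz)`` — image-style row/column for the lateral plane,
  depth last;
* physical coordinates in micrometres: ``x = ix * dx`` (fast scan axis),
  ``y = iy * dy`` (slow scan axis), ``z = iz * dz`` (depth, increasing
  downward into the skin);
* amplitudes are non-negative optoacoustic signal magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Volume", "Projection", "RawScan"]


@dataclass
class Volume:
    """A 3D optoacoustic amplitude grid with voxel spacing in µm.

    ``data`` has shape ``(ny, nx, nz)``; ``voxel`` is ``(dx, dy, dz)`` µm.
    """

    data: np.ndarray
    voxel: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if len(self.voxel) != 3 or any(v <= 0 for v in self.voxel):
            raise ValueError(f"voxel spacings must be three positive values, got {self.voxel}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def nz(self) -> int:
        return self.data.shape[2]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in µm."""
        ny, nx, nz = self.data.shape
        dx, dy, dz = self.voxel
        return (nx * dx, ny * dy, nz * dz)

    def z_coords(self) -> np.ndarray:
        """Depth coordinate of each z slice (µm, voxel centers at k*dz)."""
        return np.arange(self.nz) * self.voxel[2]


@dataclass
class Projection:
    """Maximum-amplitude projection paired with the depth index of the maximum.

    ``zero_depth`` is the depth (µm) of the most elevated above-threshold
    signal; depth-encoded renderings are relative to it.
    """

    map: np.ndarray
    depth_index: np.ndarray
    pixel: tuple[float, float]
    dz: float
    zero_depth: float = 0.0

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map)
        self.depth_index = np.asarray(self.depth_index)
        if self.map.shape != self.depth_index.shape:
            raise ValueError("map and depth_index must share a shape")

    def depth_um(self) -> np.ndarray:
        """Per-pixel depth of the maximum in µm (absolute, not relative)."""
        return self.depth_index * self.dz


@dataclass
class RawScan:
    """A stream of depth-resolved A-scans with per-pulse metadata.

    ``ascans``: (n_pulses, n_depth_samples); ``positions``: (n_pulses, 2)
    lateral pulse positions in µm; ``energies``: per-pulse relative laser
    energy (dimensionless, ≈1).  ``dz`` is the depth sample spacing in µm.
    """

    ascans: np.ndarray
    positions: np.ndarray
    energies: np.ndarray
    sample_rate: float = 250e6
    dz: float = 6.0

    def __post_init__(self) -> None:
        self.ascans = np.asarray(self.ascans)
        self.positions = np.asarray(self.positions, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        n = self.ascans.shape[0]
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_pulses, 2)")
        if self.energies.shape != (n,):
            raise ValueError("energies must be (n_pulses,)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_pulses(self) -> int:
        return self.ascans.shape[0]
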