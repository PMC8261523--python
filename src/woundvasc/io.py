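"""File I/O: volumes and projections as TIFF with JSON sidecars.

Volumes are stored as multi-page 32-bit TIFF (one page per depth slice);
voxel sizes and metadata live in a ``<name>.json`` sidecar next to the
image.  Projections are a pair of 32-bit TIFFs (amplitude, depth index)
plus a sidecar.  Edge scans travel as 2-column CSV, raw scan streams as
NPZ archives.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import Projection, RawScan, Volume
from .layers import SeparationSurface
from .resolution import EdgeScan

__all__ = [
    "save_volume",
    "load_volume",
    "save_projection",
    "load_projection",
    "save_surface",
    "load_surface",
    "save_edge_scan",
    "load_edge_scan",
    "save_raw_scan",
    "load_raw_scan",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(volume: Volume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(volume.data.astype(np.float32), 2, 0))
    meta = {k: v for k, v in volume.meta.items() if np.isscalar(v) or isinstance(v, str)}
    _sidecar(path).write_text(json.dumps({"voxel_um": list(volume.voxel), "meta": meta}))


def load_volume(path: str | Path) -> Volume:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    side = json.loads(_sidecar(path).read_text())
    return Volume(data, tuple(side["voxel_um"]), meta=side.get("meta", {}))


def save_projection(proj: Projection, prefix: str | Path) -> None:
    prefix = Path(prefix)
    tifffile.imwrite(prefix.with_suffix(".map.tif"), proj.map.astype(np.float32))
    tifffile.imwrite(
        prefix.with_suffix(".depth.tif"), proj.depth_index.astype(np.int32)
    )
    prefix.with_suffix(".proj.json").write_text(
        json.dumps(
            {"pixel_um": list(proj.pixel), "dz_um": proj.dz, "zero_depth_um": proj.zero_depth}
        )
    )


def load_projection(prefix: str | Path) -> Projection:
    prefix = Path(prefix)
    side = json.loads(prefix.with_suffix(".proj.json").read_text())
    return Projection(
        map=tifffile.imread(prefix.with_suffix(".map.tif")),
        depth_index=tifffile.imread(prefix.with_suffix(".depth.tif")),
        pixel=tuple(side["pixel_um"]),
        dz=side["dz_um"],
        zero_depth=side["zero_depth_um"],
    )


def save_surface(surface: SeparationSurface, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, surface.depth.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {
                "method": surface.method,
                "pixel_um": list(surface.pixel),
                "n_support": int(len(surface.support_points)),
            }
        )
    )


def load_surface(path: str | Path) -> SeparationSurface:
    path = Path(path)
    side = json.loads(_sidecar(path).read_text())
    return SeparationSurface(
        depth=tifffile.imread(path).astype(float),
        method=side["method"],
        pixel=tuple(side["pixel_um"]),
    )


def save_edge_scan(scan: EdgeScan, path: str | Path) -> None:
    pd.DataFrame({"x_um": scan.x, "amplitude": scan.y}).to_csv(path, index=False)


def load_edge_scan(path: str | Path) -> EdgeScan:
    df = pd.read_csv(path)
    return EdgeScan(x=df.iloc[:, 0].to_numpy(), y=df.iloc[:, 1].to_numpy())


def save_raw_scan(raw: RawScan, path: str | Path) -> None:
    np.savez_compressed(
        path,
        ascans=raw.ascans,
        positions=raw.positions,
        energies=raw.energies,
        sample_rate=raw.sample_rate,
        dz=raw.dz,
    )


def load_raw_scan(path: str | Path) -> RawScan:
    z = np.load(path)
    return RawScan(
        ascans=z["ascans"],
        positions=z["positions"],
        energies=z["energies"],
        sample_rate=float(z["sample_rate"]),
        dz=float(z["dz"]),
    )
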