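"""Run configuration: a single validated document driving the pipeline.

Every tunable default of the analysis is exposed here; the effective
configuration is written next to the outputs of each run so results are
reproducible from the run directory alone.  All randomness flows from
the single top-level ``seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # wound series generator (used when simulate=True)
    simulate: bool = True
    timepoints: tuple[float, ...] = (5.0, 7.0, 10.0, 13.0)
    initial_radius_um: float = 2500.0
    closure_k: float = 0.8
    closure_t0: float = 5.5
    field_of_view_um: tuple[float, float] = (7000.0, 7000.0)
    voxel_um: tuple[float, float, float] = (10.0, 10.0, 10.0)
    noise_sigma: float = 0.02
    # preprocessing
    band_low_hz: float = 2e6
    band_high_hz: float = 50e6
    filter_order: int = 3
    clahe_clip_limit: float = 0.01
    # vesselness / layers
    scales_small_um: tuple[float, ...] = (5.0, 10.0, 15.0)
    scales_large_um: tuple[float, ...] = (25.0, 40.0, 60.0)
    q_small: float = 0.9
    q_large: float = 0.7
    surface_offset_um: float = 30.0
    # vessels
    binarize_low: float = 0.12
    binarize_high: float = 0.30
    min_length_um: float = 30.0
    # wound aggregation
    heatmap_bin_um: float = 400.0
    heatmap_extent_um: float = 6000.0
    radial_bin_um: float = 250.0
    closing_radius_um: float = 200.0
    # optional pre-existing inputs (volume TIFFs per timepoint)
    volumes: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        if not self.simulate:
            if not self.volumes:
                raise ValueError("config error: no volumes given and simulate=False")
            for v in self.volumes:
                if not Path(v).exists():
                    raise ValueError(f"config error: missing volume path {v!r}")
        if len(self.timepoints) < 1:
            raise ValueError("config error: at least one timepoint required")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("config error: invalid filter band")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("config error: voxel sizes must be positive")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config error: unknown keys {sorted(unknown)}")
    for key in ("timepoints", "field_of_view_um", "voxel_um", "scales_small_um",
                "scales_large_um", "volumes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
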