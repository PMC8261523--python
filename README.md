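# woundvasc

Quantification of wound angiogenesis from label-free, large-scale
optoacoustic microscopy (LSOM) of mouse dorsal skin.

Healing of full-thickness excisional wounds is driven by the superficial
capillary plexus: sprouting starts as a ring of tortuous, dilated
capillaries at the wound margin and matures into straight vessels
aligned toward the wound center. `woundvasc` turns depth-resolved
optoacoustic amplitude volumes into quantitative measures of that
process:

* **Preprocessing** — third-order Butterworth band-pass (2–50 MHz,
  zero-phase) of raw A-scans, per-pulse laser-energy correction,
  regridding of the sinusoidal scan trajectory, maximum-amplitude
  projection (MAP) with the depth index of the maximum, CLAHE contrast
  compression and relative depth-encoded rendering.
* **Resolution** — edge-spread function fitted as a logistic
  y(x) = 1/(1 + e^(−k(x−x₀))) with a robust least-absolute-residual
  objective; lateral resolution reported as the FWHM of the numerically
  differentiated ESF (FWHM = 4 ln(1+√2)/k).
* **Layer separation** — multiscale (Frangi) vessel enhancement at fine
  and coarse scales gates support points on superficial capillaries;
  a separation surface (average of a scattered linear interpolation and
  a fifth-order polynomial fit) splits each volume into superficial and
  deep compartments, conserving every voxel.
* **Vessel morphometrics** — hysteresis binarization, topology-preserving
  skeletonization with branch decomposition at junctions, and per-segment
  length (µm), diameter (2 × median distance-to-background, µm),
  orientation (degrees, undirected), tortuosity (accumulated |turning
  angle| / length, °/µm) and angular alignment cos 2Δθ toward the wound
  center (+1 radial, −1 circumferential).
* **Wound-level aggregation** — wound center from the non-vascularized
  area, healing and re-vascularization scores as area ratios in [0, 1],
  logistic closure kinetics with the normalized rate curve, 400 µm ×
  400 µm heat maps over a 6 mm extent, radial profiles, and a Student's
  t-test comparing superficial and deep per-wound median diameters.
* **Phantom generator** — seeded, ground-truthed synthetic scenes
  (two-layer vasculature, healing wound time series, edge targets, raw
  A-scan streams) emulating the statistical structure of the imaging
  data, used throughout the test suite for parameter-recovery checks.

## Worked example

Measure the lateral resolution of a synthetic edge scan and run a full
simulated wound analysis:

```python
import numpy as np
from woundvasc import fit_esf, make_edge_target
from woundvasc.config import RunConfig
from woundvasc.pipeline import run_pipeline

fit = fit_esf(make_edge_target(k=0.47, x0=100.0, step=0.5))
print(f"FWHM = {fit.fwhm:.2f} µm (k = {fit.k:.2f} µm⁻¹)")

out = run_pipeline(RunConfig(out_dir="demo", seed=5))
print((out / "scores.csv").read_text())
```

prints

```
FWHM = 7.50 µm (k = 0.47 µm⁻¹)
dpw,vascularization_score,healing_score,n_vessels,center_x_um,center_y_um
5,0.383306,0.383324,1316,3508.16,3503.73
7,0.755841,0.755966,1465,3500.07,3510.62
10,0.951889,0.951907,1540,3511.2,3494.16
13,0.99358,0.993598,1322,3508.16,3503.73
```

The FWHM is the lateral resolution implied by the fitted edge steepness
(k = 0.47 µm⁻¹ ↔ 7.50 µm). Each row of `scores.csv` is one imaging
session of the simulated wound: the re-vascularization score is the
fraction of the original 5 mm wound area covered by detected vessels,
rising from ≈0.39 at 5 days post wounding to ≈0.99 at 13; `n_vessels`
counts the individual vessel segments measured per session. The run
directory also contains `vessels.csv` (one row per segment with all
morphometrics), `healing_fit.json` (logistic kinetics), per-metric heat
maps and radial profiles.

The same stages are scriptable from the shell:

```bash
woundvasc simulate --seed 1 --out phantoms/
woundvasc resolution --edge edge.csv --out fit.json
woundvasc layers --vol vol.tif --out-prefix wound1_
woundvasc analyze --config run.yaml
```

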