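# Methods

## Imaging model and coordinate conventions

The package operates on 3D grids of optoacoustic amplitude over dorsal
mouse skin. Axes are x (fast scan), y (slow scan) and z (depth,
increasing downward); arrays are indexed `(iy, ix, iz)` and all physical
quantities are micrometres and hertz. Amplitude is the magnitude of the
band-passed pressure signal, so vessels appear as bright curvilinear
structures on a dark background.

The optical-resolution scan geometry makes depth columns independent:
each laser pulse yields one A-scan at one lateral position, and volumes
are formed purely by regridding — no acoustic reconstruction
(delay-and-sum or model-based inversion) is performed or needed.

## Preprocessing

A-scans are band-pass filtered at 2–50 MHz with a third-order
Butterworth filter applied forward–backward. Zero-phase filtering is a
deliberate choice: the depth index of the amplitude maximum is used
downstream as a depth estimate, and a causal filter would shift it.
The squared magnitude response this implies is accepted (DC rejection
> 40 dB, 10 MHz within 1 dB, 100 MHz attenuated > 30 dB).

Per-pulse energy correction divides each A-scan by its recorded relative
pulse energy, inverting the known laser fluctuation exactly; round-trip
error on jittered synthetic streams is below 1e−6.

Regridding assigns each pulse to its nearest lateral grid node and
averages multiple hits. Nodes left empty by the sinusoidal trajectory
are filled from their nearest occupied neighbour and flagged in the
volume metadata; more than 5 % empty nodes logs a warning and more than
50 % is an error. The default sinusoidal density (≈3.3 pulses per
column crossing) leaves no empty nodes.

The maximum-amplitude projection takes the per-column maximum of
|amplitude| and the index of that maximum; ties take the first
(shallowest) slice, which favours superficial structures in the
relative-depth display. Zero depth is defined as the minimum depth of
the maximum over pixels above 10 % of the peak amplitude. CLAHE
(clip limit 0.01, tiles 1/8 of the image side) compresses dynamic range
for display; depth-encoded renderings map relative depth to a palette
and CLAHE amplitude to lightness.

## Resolution measurement

The edge-spread function of a scan across a sharp absorbing edge is
fitted with a four-parameter logistic (steepness k, edge location x₀,
plus amplitude and offset as nuisance parameters for non-normalized
scans). The least-absolute-residual objective is minimized by
iteratively reweighted least squares around a Levenberg–Marquardt core;
initial values are x₀ at the median crossing and k = 4/(x₈₄ − x₁₆).
Falling edges are detected from the x–y correlation and fitted on the
mirrored data. A scan qualifies only if it flattens on both sides of
the transition (smoothed tail slope < 0.5 of the central slope);
otherwise the plateau levels, and with them k, are unidentifiable.

The line-spread function is the numerical gradient of the fitted ESF on
a fine grid and the resolution is its FWHM by linear interpolation at
half maximum. For the logistic model FWHM·k = 4 ln(1+√2) ≈ 3.5255
exactly; the numerical estimate reproduces this within 0.5 % across
k ∈ [0.1, 2] µm⁻¹, and k = 0.47 µm⁻¹ yields 7.50 µm. Axial resolution
is set by the detector bandwidth and is not estimated here.

## Layer separation

Support points for the separation surface are pixels that contain small
but not large vessels. Candidates must exceed the 0.9 quantile of the
fine-scale Frangi response and 25 % of the peak amplitude (noise pixels
carry meaningless depth indices). Two rejection stages then remove
large-vessel pixels:

1. *Width gating.* The amplitude smoothed at the coarse scale
   ("persistence") stays high over wide vessels and washes out over
   capillaries; pixels above an absolute persistence of 0.32, above the
   0.7 candidate quantile of persistence, or above the 0.7 quantile of
   coarse-vesselness × persistence are dropped. The absolute cap
   matters: in a scene containing only wide vessels a purely
   quantile-based gate would still pass 70 % of candidates.
2. *Depth gating.* A robust (soft-L1) quadratic surface is pre-fitted
   to the remaining depths and points more than 35 µm deeper are
   discarded, twice. Deep vessels run ≳80 µm below the capillary
   plexus, so they separate cleanly in depth even when their width is
   ambiguous.

Vesselness for this gating is computed on the normalized raw projection,
not the CLAHE image: CLAHE equalizes thin and wide vessels so strongly
that fine- and coarse-scale responses no longer discriminate (measured
≈46 % deep contamination of support points when gating on the CLAHE
map, 0 % with the scheme above). Frangi's structureness scale γ is
fixed at 0.01 rather than auto-derived per scale; the per-scale
auto-γ renormalizes every scale to a comparable maximum and erases
cross-scale selectivity entirely. Scales are given as approximate
vessel diameters; the Gaussian scale of the Hessian is half the stated
value. Defaults: fine {5, 10, 15} µm, coarse {25, 40, 60} µm, matching
capillary (10–30 µm) and deep-vessel (35–50 µm) calibre ranges.

The surface itself is the average of a scattered linear interpolation
(accurate, noisy) and a degree-5 bivariate polynomial least-squares fit
(smooth) on centered/scaled coordinates, with rank-deficiency falling
back to lower degrees. Outside the support convex hull the surface is
continued with the nearest in-hull value — a quintic extrapolates
wildly in unsupported border bands (errors of several hundred µm were
measured). The averaged surface is smoothed with a 250 µm Gaussian
(the dermal separation varies on the millimetre scale; sub-millimetre
wiggle is support-sampling noise) and finally shifted 30 µm deeper:
support depths sit *on* capillaries, whereas the separation must pass
between the layers; 30 µm ≈ 3× the median capillary radius. Splitting
assigns a voxel superficial iff its depth is strictly above the surface;
superficial + deep reproduce the original volume exactly, element-wise.

On two-layer phantoms at the default scene size this recovers the true
surface with RMS error well below 40 µm and assigns ≥ 99.9 % of true
superficial vessel voxels to the superficial compartment.

## Vessel morphometrics

Binarization is hysteresis-like: seed pixels need > 30 % of peak
amplitude *and* fine-scale vesselness above its 0.75 quantile (this
suppresses blobs and speckle); regions grow over pixels above 12 % of
peak. The map is smoothed by 1 px before thresholding so pixel noise
neither perforates the boundary nor seeds isolated speckle. The 12 %
growth threshold is deliberate: rendered vessels have Gaussian profiles
with σ = r/2, for which the exp(−2) ≈ 13.5 % contour sits exactly at
the nominal radius, so the mask boundary tracks the physical vessel
wall. Objects under 5 px are removed.

The skeleton (topology-preserving thinning) is cut at junction pixels
(≥ 3 skeleton neighbours); each branch is ordered into a pixel path,
converted to µm, and discarded if shorter than 30 µm (≈ 4× the lateral
resolution; segments below that are spurs and noise).

Diameter is 2 × median distance-to-background along the centerline.
The distance map is computed at 4× lateral upsampling of the raw
amplitude (bilinear), thresholded at the same 12 % level and restricted
to the detected mask's neighbourhood, minus half a fine pixel (the EDT
measures to background pixel centers, overshooting the boundary).
Without the upsampling, boundary quantization at 5–10 µm pixels
dominates the error of capillary-sized diameters. Diameters at the
resolution limit remain overestimated — a 10 µm vessel cannot measure
below the ≈2-pixel footprint it occupies — which mirrors the behaviour
of the imaging system itself near its resolution limit. Median relative
error over 10–50 µm tubes at 5 µm pixels is ≈10 %.

Tortuosity is the summed absolute turning angle between consecutive
chords divided by path length (°/µm), computed on a moving-average
smoothed copy of the centerline (window 5 px): unsmoothed pixel
skeletons of straight lines have a staircase turning rate of
≈0.4 °/µm at 10 µm pixels, which the smoothing suppresses while
curvature at and above the ≈30 µm scale is preserved (straight → 0
exactly; semicircle of radius r → (180/π)/r within 1 %).

Alignment is cos 2Δθ between the segment's end-to-end orientation
(undirected, folded to [0, 180)) and the radial direction from the
wound center to the segment midpoint: +1 radial, −1 circumferential,
0 in expectation under isotropy. Segments whose midpoint coincides with
the center are excluded and logged.

## Wound-level aggregation

The vascularized-area mask is derived from the binary vessel mask by
disk closing with a 200 µm radius (realized with two exact Euclidean
distance transforms, which is both exact for disks and fast at
physically large radii) followed by filling only holes smaller than
400 µm across. Unconditional hole-filling would erase the avascular
wound core as soon as a sprout ring encircles it; the bounded fill
removes inter-vessel gaps while preserving any genuine wound larger
than the cutoff.

The wound center is the centroid of the largest non-vascularized
connected component, ignoring components that touch the image border
whenever an interior component exists (border gaps are coverage
artifacts; the wound is interior by the imaging protocol). Across a
time series the wound is re-located within half the initial radius of
the previous center — wounds do not move between sessions — and once
the largest candidate falls below 2 % of the initial wound area the
wound is considered closed beyond detectability and the previous center
is kept.

Healing score = (initial − current wound area)/initial;
re-vascularization score = re-vascularized area within the original
wound / initial area; both clipped to [0, 1], with wound expansion
beyond 5 % logged. Closure dynamics are summarized by a least-squares
logistic fit over days post wounding (dpw); the healing rate is the
normalized time derivative of the fit, whose peak sits at the midpoint
t₀ by symmetry. Degenerate score series (no closure signal) are
rejected rather than fitted.

Heat maps pool vessels across wounds relative to each wound's center
into 400 µm × 400 µm bins over a 6 mm extent (vessels pooled first,
binned second, so wounds with more vessels weigh more); empty bins are
NaN, never zero. Radial profiles average metrics per annulus per dpw
with the vessel count attached; empty annuli are absent. The
superficial/deep calibre comparison is an equal-variance Student's
t-test on per-wound median diameters (Welch variant by flag), with
normal-theory 95 % confidence intervals; no multiple-testing correction
is applied as only one comparison is in scope.

## Synthetic phantoms

The generator provides ground-truthed scenes whose statistical structure
matches what the analysis assumes; every random draw flows from one
integer seed and outputs are bit-reproducible.

*Vessels* are Gaussian-profile tubes, amplitude = exp(−d²/2σ²) with
σ = radius/2, rendered segment-wise with exact point-to-segment
distances and max-combination; a voxel counts as inside a vessel at
amplitude ≥ exp(−2), i.e. within the nominal radius. The smooth profile
mimics band-limited optoacoustic signals and exercises diameter
estimation realistically; tubes thinner than two voxels along the
finest axis are rejected as unresolvable.

*Two-layer scenes* (default 7 × 7 mm², 1.5 mm deep, 10 µm lateral /
5 µm axial voxels — a working resolution chosen to keep full scenes
comfortably computable; a 5 µm lateral step is available by config)
separate tortuous superficial capillaries (diameters 10–30 µm, 25–60 µm
above a smooth quadratic separation surface at ≈250 µm mean depth) from
straighter deep vessels (35–50 µm, 80–250 µm below it). Capillary
tortuosity is produced by a random-walk heading with von-Mises turning
increments calibrated to a target turning rate in °/µm.

*Wound series* place a circular wound (default initial radius 2500 µm,
i.e. 5 mm diameter) whose closure score follows a logistic with
steepness 0.8 day⁻¹ and midpoint 5.5 dpw — the logistic through cohort
mean re-vascularization of ≈40/72/96/99 % at 5/7/10/13 dpw. The
avascular disk covers a fraction (1 − score) of the initial *area*
(radius = r₀√(1−s)), so measured area-ratio scores recover the
generator's settings directly. Each timepoint contains: a jittered-grid
background network (pitch 300 µm — below twice the 200 µm closing
radius, as real capillary networks are below it too, so coverage closes
into a connected vascularized area); a ring of tortuous, dilated
(25–40 µm) sprouts hugging the current margin from outside with a
square-law bias toward the inner edge; and radially aligned vessels on
a jittered polar lattice filling the re-vascularized annulus, their
orientation scatter set by a per-dpw alignment schedule (mean cos 2δ
with δ uniform in ±a). In-wound turning rates fall as alignment rises
(ring: 1.3 − 0.8·alignment °/µm; radial: 0.05 + 0.5·(1 − alignment)),
emulating sprout maturation. Walks step 30 µm so that their curvature
is visible at 10 µm voxels.

*Edge targets* sample the logistic ESF on a grid centered on the edge;
*raw scans* serialize a volume into per-pulse A-scans along raster or
sinusoidal trajectories with uniform per-pulse energy jitter.

What the phantoms do **not** emulate: speckle and depth-dependent
attenuation (noise is additive Gaussian on amplitude, default σ = 0.02),
acoustic wave propagation beyond an optional Gaussian PSF blur
(7.5 µm lateral / 35 µm axial FWHM), motion and breathing artifacts,
eschar obscuration, skin curvature in the projected wound area, and the
biological variability of real vascular networks. Passing
parameter-recovery tests on these phantoms therefore demonstrates that
the measurement chain is unbiased under its own model assumptions, not
that those assumptions hold for any particular instrument or animal.

## Problem sizes and numerical choices

The test suite and the acceptance script run phantoms at 3.5–7 mm
fields of view with 10 µm lateral voxels, 20 seeded scenes for the
layer-separation study, 36 calibration tubes spanning 10–50 µm at 5 µm
pixels, 100 noise seeds for the kinetics study, and 10⁵ orientations
for the isotropy check — sizes chosen so the whole validation completes
in a few minutes while keeping every estimate's sampling error well
below the tolerance it is tested against. Ties in the projection
argmax take the shallowest slice; degenerate fits (rank-deficient
polynomial surfaces, zero-variance t-test groups, non-spanning edge
scans, all-zero score series) are either reduced in order or rejected
with explicit errors, never silently patched.

## Known limitations

Vessel analysis is 2D on the projection with per-point depth
annotation; lengths and tortuosities of steeply diving vessels are
in-plane projections. Diameters near the lateral resolution are
overestimated and no deconvolution-based correction is attempted.
The alignment score's cos 2Δθ form is a declared convention for
"orientation toward the wound center"; other conventions would rescale,
but not reorder, group comparisons. The healing score uses flat
projected areas without skin-curvature correction. Cross-timepoint
image registration is out of scope; the wound-center tracking assumes
the imaged field does not shift grossly between sessions.
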