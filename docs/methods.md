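# Methods

This note records the models, conventions, parameter choices and known
limitations behind `scopeloop`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Pixel coordinates are 0-based `(x, y)` with `x` rightward (column) and
`y` downward (row); a pixel's centre sits at integer coordinates, so
pixel `(0, 0)` covers `[-0.5, 0.5)²`. Sub-pixel positions are carried as
floats everywhere; rounding happens only at rasterisation. A consequence
worth spelling out: a scan band of columns `k·l_p .. k·l_p + l_p − 1` has
central coordinate `k·l_p + (l_p − 1)/2`, i.e. 34.5 for band 3 at
`l_p = 10`, not 35. Mixing the two conventions injects a half-pixel
translation into the calibration, which the identity-recovery tests
would catch.

The camera default frame is 1920 × 1088 (the HQ sensor readout at 10×,
1.25 µm/px); the projector default is 640 × 360 — DLP pixel grids vary by
model, so this is only a configurable default and no algorithm depends
on it. Tests and the acceptance script use 384 × 216 frames (same aspect)
so that full calibrations, scans and loop runs finish in seconds; every
algorithm is resolution-independent.

## Calibration

The transform is modelled as affine (6 parameters). This covers rotation
between the frames, anisotropic scale and the shear produced by a
modestly tilted projection axis; it does not model perspective
(homography) or lens distortion, which is out of scope.

**Region detection.** The illuminable region is thresholded on the
difference between a flood-lit and a dark capture. Dark-frame
subtraction is applied before every threshold and every scan
measurement, making the threshold refer to projector light only — scene
appearance and background level drop out exactly (up to noise). Only the
largest connected component is kept, rejecting stray-light specks near
the borders.

**Zone placement.** Scan zones head toward the corners of the region's
bounding box with per-axis offset `(1 − b)·h + b·s_c/2` from the centre
(`h` = bbox half-extent). At `b = 0` centres lie exactly on the bbox
border; at `b = 1` the four zone squares pack mutually adjacent around
the centre; the offset interpolates linearly and monotonically between.
A zone whose square does not intersect the region mask is nudged toward
the bbox centre until it does; a region that cannot host the requested
disjoint zones is an error. Default `b = 1/3`: far enough from the
border to avoid stray-light artefacts, wide enough apart that the
least-squares fit is well conditioned. Default `n_zones = 4` (three is
the affine minimum; the fourth adds redundancy).

**Hyper-parameter sizing.** `l_p = 10` projector px by default — smaller
values improve localisation but multiply the number of captures. The
zone breadth `s_c = 2·M·l_p` is rounded up to the next odd integer so a
zone has a well-defined centre pixel. The magnification *M* can be (a)
supplied directly, (b) computed from user-reported grid observations via
`M = g_c·G_p/(G_c·g_p)` — here `g_c` denotes the observed size of a
*projected* grid square and `g_p` that of a *reference* square, the
convention under which the relation is consistent with `l_c = M·l_p` —
or (c) measured automatically: a grid of spacing `G_p` is projected, the
dominant pitch of the captured image is read off the nearest
autocorrelation side peak (side peaks above 45% of the zero-lag energy;
robust to rotation, blur and noise), and fed through the same relation
with `g_p = G_c = G_p`. If no reliable pitch is found, or it disagrees
wildly with the footprint-area estimate `sqrt(area / projector area)`,
the area estimate is used instead with a warning. *M* only sizes the
zones, so ~10% accuracy is ample; the automatic route is typically ~1%.

**Peak localisation.** The response of a zone across bands is the
overlap of a box aperture (the zone square, warped to projector
coordinates) with the band partition. Three estimators are provided via
`peak_mode`:

- `halfmass` (default): spread each band's response uniformly over its
  pixel extent and take the interpolated half-mass (median) point. For a
  box-shaped aperture this is *exact* regardless of the aperture's width
  or phase relative to the band grid, and it remains exact under
  symmetric blur; it is also the most outlier-resistant of the three.
- `centroid`: intensity-weighted mean of band centres. Biased by up to
  ~0.2 px when the (odd) zone breadth is not a multiple of `l_p`,
  because the partial band's mass is attributed to its centre.
- `argmax`: the single highest band, ties broken toward the lower index
  — the bluntest reading of "the bands with the highest intensities",
  kept for strict comparison; quantised to one band.

Bands below 2% of the zone's peak are ignored as noise (`peak_floor_frac`).
A zone whose peak response does not clear `contrast_floor` (default 5×
the dark-frame noise MAD) is excluded with a warning; dropping below
three zones aborts. Measured on 20 random benches, `halfmass` brings the
median frame-wide reprojection error from ~0.8 px (truncated centroid)
to ~0.03 px; the test suite asserts the < 2 px requirement, not these
figures.

**Correspondences and fit.** The camera-side point of each
correspondence is the centre of the pixel square actually averaged over
(nominal centre rounded to the grid, adjusted for frame clipping), not
the nominal float centre — eliminating a ≤ 0.5 px bookkeeping mismatch.
The affine fit is a plain least-squares solve of the 6 parameters;
collinear camera points or fewer than three pairs raise a degeneracy
error. RMS reprojection residuals above `residual_warn` (3 projector px)
warn but do not fail, since a large residual can reflect genuine
non-affine optics.

The interactive mode is a thin prompt layer (injectable `input_fn` /
`echo`, so it is testable headlessly) over exactly the batch pipeline.

## Virtual bench

Rendering pipeline: scene brightfield (or uniform background) **+**
pattern warped by the ground-truth projector→camera affine (bilinear),
masked to the illuminable footprint and multiplied by a radial vignette
**→** Gaussian blur **→** additive Gaussian noise **→** clip to
[0, 255], 8-bit. The vignette applies to the projection contribution
only — physically it lives in the projection path, and a dark capture is
then uniform as expected. Noise is drawn from
`SeedSequence(rng_seed, capture_index)`: the whole capture sequence is
reproducible for a given seed, but successive captures differ the way
real sensor reads do (per-frame identical noise would cancel exactly in
dark-frame subtraction and hide the noise sensitivity the calibration
should be tested against). No shot-noise or optics-accurate PSF model is
attempted; additive Gaussian noise plus Gaussian blur is the simplest
model that stresses the thresholding and peak-finding steps.

`random_bench` samples the study conditions used throughout the tests:
rotation uniform in ±10°, scale log-uniform in [0.5, 2], translation
uniform within ±25% of the camera frame, blur uniform in [0, 2] px,
noise σ uniform in [0, 4]. The projector frame is sized ≈ 1.6× the
camera frame divided by the scale, so the footprint covers the whole
camera frame even at the largest translation — real builds aim the
projector to cover the full field of view, and it makes "frame-wide"
error a well-posed quantity.

## Scratch-assay scene

The monolayer is a camera-frame occupancy field whose wound is a band
bounded by two per-row sub-pixel front positions (a vertical band by
default; horizontal is the transpose). Fronts are straight lines plus
optional sinusoidal modulation and band-limited random roughness.
Because the fronts are the state, exact ground-truth edge polylines are
always available as an evaluation oracle the detector never sees, and
the rendered occupancy is just a thresholded view.

Appearance: monolayer 140 counts plus band-limited texture (std 10,
correlation 4 px), wound 200 counts — the usual brightfield polarity for
a confluent sheet against cell-free substrate; both levels are
configurable, and the segmenter's `polarity="auto"` simply takes the
larger region as monolayer (valid whenever the wound is narrower than
the sheet).

Dynamics: each front advances into the wound at `v` µm/h, converted at
1.25 µm/px; a front row whose position lies within 2 px of an on-pixel
of the supplied illumination mask advances at `v·(1 + g)` instead —
light-stimulated migration is modelled as a *local* speed-up of lit
front cells, not of the whole sheet. Fronts never retreat, rows where
the fronts meet stay met, so wound area is non-increasing and a closed
wound is a fixed point. Default `v = 10` µm/h per front closes a 500 µm
scratch in about a day — a typical epithelial scratch-assay scale chosen
as a simulation default, not a measured biological constant. The gain
`g` is a free behavioural knob (tests use `g = 1`, i.e. lit cells twice
as fast); no dose–response or phototoxicity model is implied.

What passing tests therefore show — and do not show: the software stack
(calibration, detection, scheduling, pattern mapping) closes the loop
correctly against a geometrically and photometrically plausible imaging
model; they say nothing about real cell behaviour, staining variability,
debris, focal drift, or non-affine optics.

## Wound targeting

Percentile contrast stretch (2–98%) or CLAHE, Otsu or fixed threshold
(the fixed threshold applies to raw 8-bit values), morphological closing
(disk, radius 2) and small-object/hole removal (64 px). Boundary
contours are traced at the 0.5 level; contour points within
`edge_margin_px` (default 8) of the image border are discarded and each
contour splits into maximal surviving chains — so the returned edge is
never a frame-border artefact. The single longest chain is the leading
edge; `return_all` exposes every chain (e.g. both fronts), and the
closed loop prefers, among chains at least half the longest, the one
nearest the previously tracked front, preventing front-swapping between
cycles. Edges are Douglas–Peucker-simplified (0.5 px) before mapping, to
bound the coordinate list handed to the projector; mapped edges are
rasterised by exact distance-to-segment (`≤ thickness/2`), clipped to
the projector frame, with an all-off pattern and a warning if the edge
maps entirely outside.

## Closed loop

Timelines include `t = 0` (capture, and by default project,
immediately), so "every P for D" yields `floor(D/P) + 1` events; the
projection period must be an integer multiple of the imaging period, and
captures precede projections at shared instants so a projection always
uses the frame just captured. The per-projection exposure has no
principled default from hardware; the library defaults to the full
projection period (continuous illumination between updates) and the CLI
exposes it explicitly. Simulated time advances by schedule deltas (a
hardware adapter would sleep; the engine never assumes which), and the
illumination passed to the scene is the projected pattern warped through
the *ground-truth* transform — what the sample actually receives, not
what was intended. Captures are plain brightfield: on the instrument the
camera does not see the projection wavelength through the emission
filter. A failed edge detection logs a warning and re-projects the
previous pattern; the loop never aborts. On a virtual bench each
projection records the distances from back-mapped pattern pixels to the
exact wound front, and `tracking_correlation` correlates the pattern
centroid's cumulative displacement along the wound normal with the true
front's (cumulative positions rather than per-step increments: with a
near-constant migration speed the increment series is
noise-dominated and its correlation meaningless, while the position
series directly expresses "the pattern follows the edge").

## Problem sizes and runtimes

Tests and acceptance use 384 × 216 camera frames, 20 random benches for
recovery, 3 sinusoidal scenes for edge accuracy, and 6-hour loops at
30-minute cadence (13 projection events); the whole suite runs in well
under a minute of compute for the simulations. These sizes are the
package's chosen defaults for its own verification; all entry points
accept full-size frames.

## Known limitations

- Affine optics only; no homography or distortion correction.
- The scene model has no single-cell resolution, no leader-cell
  phenotype, and healing speed is prescribed, not emergent.
- Automatic grid magnification assumes several grid periods are visible
  inside the illuminable region; degenerate cases fall back to the
  footprint-area estimate.
- The folder bench replays pre-captured images; live hardware drivers
  (GPIO/DLP, stage, filters) are intentionally out of scope.
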