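# scopeloop

Projector–camera calibration and closed-loop targeted illumination for
patterned-light microscopy, with a built-in virtual optical bench.

Open microscope platforms that combine a camera with a digital light
projector (DLP) can illuminate a living sample with arbitrary pixel
patterns — for example, tracing near-UV light along the leading edge of a
healing scratch wound in an epithelial monolayer, where localised
DNA-damage signalling is known to accelerate cell migration. Doing this
autonomously requires three pieces of software, which this package
provides in hardware-independent form:

1. **Calibration** (`scopeloop.calibration`) — recover the camera →
   projector affine transform with no prior knowledge of the optics, by
   banded structured-light scanning:
   - flood-illuminate the projector and threshold the camera difference
     image to find the *illuminable region*;
   - sweep bands of `l_p` adjacent projector columns (then rows),
     recording the intensity in a handful of square camera-frame *scan
     zones*;
   - localise each zone's projector position from the bands with the
     highest responses, and fit the 6-parameter affine map
     camera → projector by least squares.

   Hyper-parameters self-tune to the unknown magnification *M*: a scan
   line of `l_p` projector px appears `l_c = M·l_p` camera px wide, and a
   zone must intercept at least two scan lines, so its breadth is
   `s_c ≈ 2·M·l_p`. *M* itself comes from comparing a projected grid
   (spacing `G_p` projector px) with a reference grid (spacing `G_c`
   camera px) through the observed square sizes `g_p`, `g_c`:
   `M = g_c·G_p / (G_c·g_p)`, giving the one-shot sizing rule
   `s_c ≈ 2·l_p·g_c·G_p / (G_c·g_p)`. A border variable `b ∈ [0, 1]`
   places the scan zones between the region border (`b = 0`, maximal
   leverage) and mutually adjacent at its centre (`b = 1`); `b = 1/3` is
   a good compromise.

2. **Wound targeting** (`scopeloop.targeting`) — brightfield frame →
   segmentation → longest continuous boundary chain (excluding
   frame-border artefacts) → polyline mapped through the calibration →
   rasterised projector pattern.

3. **Closed loop** (`scopeloop.loop`) — schedule periodic captures and
   projections (e.g. images every 5 min, light every 30 min), re-running
   the edge detector each cycle so the projected pattern follows the
   moving front, with full logging and fail-safe re-projection.

The **virtual bench** (`scopeloop.bench`) simulates the projector →
sample → camera light path (ground-truth affine warp, vignetting, blur,
noise, partial coverage) and a healing scratch-assay monolayer with
sub-pixel wound fronts, optional light-accelerated migration, and exact
ground-truth edges — so every component above is testable without
hardware, against known truth.

## Worked example

Calibrate a randomly warped virtual bench (rotation, scale, translation,
blur, noise all unknown to the algorithm) and compare with its ground
truth:

```python
import numpy as np
import scopeloop as sl

model = sl.random_bench(1, camera=sl.FrameSpec(384, 216, "camera"))
bench = sl.VirtualBench(model)
result = sl.calibrate(bench)

print(f"M = {result.params_used.M:.3f}  (true scale {model.ground_truth_map.mean_scale:.3f})")
print(f"s_c = {result.params_used.s_c} camera px, residual = {result.residual:.4f} projector px")
pts = np.array([(x, y) for x in np.linspace(0, 383, 20) for y in np.linspace(0, 215, 12)])
err = np.linalg.norm(result.map.apply(pts) - model.ground_truth_map.inverse().apply(pts), axis=1)
print(f"frame-wide error vs ground truth: mean {err.mean():.3f} px, max {err.max():.3f} px")
```

prints

```
M = 1.870  (true scale 1.867)
s_c = 39 camera px, residual = 0.0077 projector px
frame-wide error vs ground truth: mean 0.014 px, max 0.028 px
```

The grid measurement recovered the optical magnification to 0.2%, sized
the scan zones accordingly, and the fitted affine reproduces the (inverse
of the) hidden ground-truth transform everywhere in the frame to a few
hundredths of a pixel.

The same flow from the shell, ending with a closed-loop run on a
simulated scratch assay (outputs under `run1/`: `frames/`, `patterns/`,
`overlays/`, `log.jsonl`, `summary.json`):

```
$ scopeloop run-loop --camera 384x216 --wound-width-um 200 \
    --imaging-min 30 --projection-min 30 --duration-h 2 \
    --thickness 5 --outdir run1 --seed 7
calibrating virtual bench ...
5 captures, 5 projections; wound area 34885 -> 27973 px^2; mean tracking error 1.51 px
```

The wound area shrinks as the fronts migrate; the projected pattern stays
within ~1.5 px of the true (hidden) wound edge at every projection. Other
commands: `scopeloop simulate` (synthetic time-lapse with ground-truth
sidecar), `scopeloop calibrate` (virtual bench or offline
pattern/capture folders from real hardware), `scopeloop detect-edge`
(single frame → pattern + overlay).

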