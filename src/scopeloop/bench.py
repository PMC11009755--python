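"""Virtual optical bench: projector -> sample -> camera light path plus a
dynamic scratch-assay monolayer.

The bench lets the calibration, targeting and closed-loop machinery run
without hardware.  A :class:`BenchModel` holds the ground-truth projector ->
camera transform and the optical imperfections (blur, additive noise,
vignetting of the projection path, partial coverage).  A :class:`SceneState`
holds a simulated epithelial monolayer with a scratch wound whose two fronts
migrate inward over time; illumination can locally accelerate a front,
emulating light-stimulated migration at the leading edge.

Scene geometry is kept sub-pixel: each wound front is a per-row real-valued
x position (for a vertical wound band), so exact ground-truth edge polylines
are always available to evaluate detectors against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, warp

from .geometry import CAMERA_FRAME, PROJECTOR_FRAME, AffineMap, FrameSpec, Polyline
from .units import PIXEL_SIZE_UM

__all__ = [
    "BenchError",
    "WoundClosedError",
    "BenchModel",
    "ScratchParams",
    "SceneState",
    "make_scratch_scene",
    "render_camera_view",
    "step_scene",
    "ground_truth_edge",
    "ground_truth_edges",
    "VirtualBench",
    "FolderBench",
    "random_bench",
]


class BenchError(RuntimeError):
    """Invalid bench input (frame mismatch, missing capture, ...)."""


class WoundClosedError(RuntimeError):
    """Requested a wound front but the wound has fully closed."""


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

@dataclass
class BenchModel:
    """Physical configuration of the simulated projector/camera pair.

    ``ground_truth_map`` maps projector pixel coordinates to camera pixel
    coordinates; it is what calibration tries to recover (inverted).
    """

    ground_truth_map: AffineMap
    camera: FrameSpec = CAMERA_FRAME
    projector: FrameSpec = PROJECTOR_FRAME
    blur_sigma: float = 0.0          # optical blur, camera px
    noise_sigma: float = 0.0         # additive Gaussian read noise, intensity units
    vignette_strength: float = 0.0   # radial falloff of projected light, [0, 1]
    illum_coverage: float = 1.0      # fraction of camera frame reachable by light
    background_level: float = 20.0   # camera counts with no light and no sample
    rng_seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if abs(self.ground_truth_map.det) < 1e-12:
            raise BenchError("ground_truth_map must be invertible")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise BenchError("blur_sigma and noise_sigma must be >= 0")
        if not (0.0 <= self.vignette_strength <= 1.0):
            raise BenchError("vignette_strength must be in [0, 1]")
        if not (0.0 < self.illum_coverage <= 1.0):
            raise BenchError("illum_coverage must be in (0, 1]")

    # cached, geometry-only quantities ------------------------------------
    def footprint(self) -> np.ndarray:
        """Boolean camera-frame mask of pixels projector light can reach."""
        if "footprint" not in self._cache:
            ones = np.ones(self.projector.shape, dtype=float)
            fp = self._warp_to_camera(ones) >= 0.5
            if self.illum_coverage < 1.0:
                h, w = self.camera.shape
                cx, cy = self.camera.center
                half_w = w * math.sqrt(self.illum_coverage) / 2.0
                half_h = h * math.sqrt(self.illum_coverage) / 2.0
                X, Y = np.meshgrid(np.arange(w), np.arange(h))
                fp &= (np.abs(X - cx) <= half_w) & (np.abs(Y - cy) <= half_h)
            self._cache["footprint"] = fp
        return self._cache["footprint"]

    def vignette(self) -> np.ndarray:
        """Radial gain map applied to the projection path."""
        if "vignette" not in self._cache:
            h, w = self.camera.shape
            cx, cy = self.camera.center
            X, Y = np.meshgrid(np.arange(w), np.arange(h))
            r2 = ((X - cx) ** 2 + (Y - cy) ** 2) / (cx**2 + cy**2)
            self._cache["vignette"] = 1.0 - self.vignette_strength * r2
        return self._cache["vignette"]

    def _warp_to_camera(self, projector_image: np.ndarray) -> np.ndarray:
        """Bilinear warp of a projector-frame image into the camera frame."""
        inv = AffineTransform(matrix=self.ground_truth_map.inverse().as_homogeneous())
        return warp(
            np.asarray(projector_image, dtype=float),
            inverse_map=inv,
            output_shape=self.camera.shape,
            order=1,
            mode="constant",
            cval=0.0,
            preserve_range=True,
        )


def render_camera_view(
    model: BenchModel,
    pattern: np.ndarray | None = None,
    scene: "SceneState | None" = None,
    noise_index: int = 0,
) -> np.ndarray:
    """Render one 8-bit camera capture.

    Pipeline: scene brightfield base (or uniform background), plus the
    projector pattern warped through the ground-truth transform, masked to
    the illuminable footprint and vignetted; then Gaussian blur, additive
    Gaussian noise, and clipping to [0, 255].

    ``noise_index`` selects an independent, reproducible noise draw; bench
    wrappers advance it per capture so repeated captures differ the way
    successive sensor reads do, while the whole sequence stays deterministic
    for a given ``rng_seed``.
    """
    if scene is not None and scene.params.camera.shape != model.camera.shape:
        raise BenchError("scene frame does not match the bench camera frame")
    if scene is not None:
        img = scene.brightfield()
    else:
        img = np.full(model.camera.shape, float(model.background_level))
    if pattern is not None:
        pattern = np.asarray(pattern)
        if pattern.shape != model.projector.shape:
            raise BenchError(
                f"pattern frame mismatch: got {pattern.shape}, "
                f"projector is {model.projector.shape}"
            )
        contrib = model._warp_to_camera(pattern.astype(float))
        img = img + contrib * model.footprint() * model.vignette()
    if model.blur_sigma > 0:
        img = ndi.gaussian_filter(img, model.blur_sigma)
    if model.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(model.rng_seed) & 0x7FFFFFFF, int(noise_index)])
        )
        img = img + rng.normal(0.0, model.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# scratch-assay scene
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScratchParams:
    """Parameters of the simulated scratch-assay monolayer.

    The monolayer renders darker (default 140 counts) than the cell-free
    wound (default 200 counts), the usual brightfield contrast polarity for
    a confluent epithelial sheet; both levels are configurable.  The default
    healing speed of 10 um/h per front closes a 500 um scratch in about a
    day, a typical epithelial scratch-assay scale; it is a simulation
    default, not a measured biological constant.
    """

    camera: FrameSpec = CAMERA_FRAME
    wound_width_um: float = 500.0
    orientation: str = "vertical"        # wound band runs top-to-bottom
    roughness_px: float = 4.0            # random front roughness (std, px)
    roughness_corr_rows: float = 12.0    # along-front correlation length
    sine_amplitude_px: float = 0.0       # optional sinusoidal front modulation
    sine_period_px: float = 120.0
    heal_rate_um_per_h: float = 10.0     # migration speed of each front
    light_gain: float = 0.0              # fractional speed-up under illumination
    monolayer_level: float = 140.0
    wound_level: float = 200.0
    texture_amplitude: float = 10.0      # band-limited texture std, counts
    texture_corr_px: float = 4.0
    pixel_size_um: float = PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be 'vertical' or 'horizontal'")
        if self.light_gain < 0:
            raise ValueError("light_gain must be >= 0")


@dataclass(frozen=True, eq=False)
class SceneState:
    """Monolayer occupancy and wound-front geometry at one time point.

    The two wound fronts are stored as per-row sub-pixel positions along the
    wound-normal axis (``left_x`` / ``right_x`` in the internal, vertical
    orientation).  Pixel occupancy and the brightfield image are derived
    views; the fronts themselves are the exact ground truth.
    """

    params: ScratchParams
    left_x: np.ndarray
    right_x: np.ndarray
    texture: np.ndarray
    time_h: float = 0.0
    rng_seed: int = 0

    @property
    def _internal_shape(self) -> tuple[int, int]:
        h, w = self.params.camera.shape
        return (h, w) if self.params.orientation == "vertical" else (w, h)

    def occupancy(self) -> np.ndarray:
        """Boolean camera-frame mask, True where the monolayer sits."""
        rows, cols = self._internal_shape
        x = np.arange(cols, dtype=float)
        wound = (x[None, :] > self.left_x[:, None]) & (
            x[None, :] < self.right_x[:, None]
        )
        occ = ~wound
        return occ if self.params.orientation == "vertical" else occ.T

    def brightfield(self) -> np.ndarray:
        """Noise-free brightfield appearance (float, camera counts)."""
        p = self.params
        occ = self.occupancy()
        tex = self.texture if p.orientation == "vertical" else self.texture.T
        img = np.where(occ, p.monolayer_level + tex, p.wound_level)
        return img.astype(float)

    @property
    def wound_area_px(self) -> float:
        """Open wound area in px^2 (sub-pixel, from the front positions)."""
        return float(np.sum(np.clip(self.right_x - self.left_x, 0.0, None)))

    @property
    def is_closed(self) -> bool:
        return bool(np.all(self.right_x - self.left_x <= 1e-9))


def make_scratch_scene(
    params: ScratchParams | None = None, seed: int = 0, **overrides
) -> SceneState:
    """Generate a scratched monolayer with roughened (optionally sinusoidal)
    wound fronts.  Deterministic for a given seed."""
    if params is None:
        params = ScratchParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    width_px = params.wound_width_um / params.pixel_size_um
    if width_px <= 0:
        raise ValueError(f"wound width must be positive, got {width_px} px")
    rows, cols = (
        params.camera.shape
        if params.orientation == "vertical"
        else params.camera.shape[::-1]
    )
    if width_px >= cols - 4:
        raise ValueError(
            f"wound width {width_px:.0f} px does not fit the "
            f"{cols} px frame extent"
        )
    rng = np.random.default_rng(seed)
    centre = (cols - 1) / 2.0
    y = np.arange(rows, dtype=float)
    sine = (
        params.sine_amplitude_px
        * np.sin(2.0 * math.pi * y / params.sine_period_px)
        if params.sine_amplitude_px > 0
        else np.zeros(rows)
    )

    def rough() -> np.ndarray:
        if params.roughness_px <= 0:
            return np.zeros(rows)
        r = ndi.gaussian_filter1d(
            rng.standard_normal(rows), params.roughness_corr_rows, mode="reflect"
        )
        sd = r.std()
        return r * (params.roughness_px / sd) if sd > 0 else np.zeros(rows)

    left = centre - width_px / 2.0 + sine + rough()
    right = centre + width_px / 2.0 + sine + rough()
    left = np.clip(left, 1.0, cols - 2.0)
    right = np.clip(np.maximum(right, left + 1.0), 1.0, cols - 2.0)
    texture = ndi.gaussian_filter(
        rng.standard_normal((rows, cols)), params.texture_corr_px
    )
    sd = texture.std()
    if sd > 0:
        texture = texture * (params.texture_amplitude / sd)
    return SceneState(
        params=params, left_x=left, right_x=right, texture=texture, rng_seed=seed
    )


def step_scene(
    scene: SceneState, dt_h: float, illumination: np.ndarray | None = None
) -> SceneState:
    """Advance the healing wound by ``dt_h`` hours.

    Each front pixel advances into the wound by ``v * dt`` (in px), or
    ``v * (1 + g) * dt`` where the local front lies under an on-pixel of
    ``illumination`` (a camera-frame boolean mask of the light the sample
    actually received).  Fronts never retreat; rows where the fronts meet
    stay met, so the wound area is non-increasing and a closed wound is a
    fixed point.
    """
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    p = scene.params
    v_px = p.heal_rate_um_per_h / p.pixel_size_um
    adv = v_px * dt_h
    rows, cols = scene._internal_shape
    left, right = scene.left_x.copy(), scene.right_x.copy()
    if adv > 0 and not scene.is_closed:
        if illumination is not None and p.light_gain > 0:
            ill = np.asarray(illumination, dtype=bool)
            if ill.shape != p.camera.shape:
                raise BenchError("illumination mask does not match camera frame")
            if p.orientation == "horizontal":
                ill = ill.T
            # a front counts as lit if light lands within 2 px of it
            ill = ndi.binary_dilation(ill, structure=np.ones((1, 5), dtype=bool))
            rows_idx = np.arange(rows)
            lit_l = ill[rows_idx, np.clip(np.rint(left).astype(int), 0, cols - 1)]
            lit_r = ill[rows_idx, np.clip(np.rint(right).astype(int), 0, cols - 1)]
        else:
            lit_l = lit_r = np.zeros(rows, dtype=bool)
        open_rows = right - left > 1e-9
        adv_l = np.where(lit_l, adv * (1.0 + p.light_gain), adv)
        adv_r = np.where(lit_r, adv * (1.0 + p.light_gain), adv)
        nl = np.where(open_rows, left + adv_l, left)
        nr = np.where(open_rows, right - adv_r, right)
        crossed = nl > nr
        mid = (nl + nr) / 2.0
        left = np.where(crossed, mid, nl)
        right = np.where(crossed, mid, nr)
    return replace(scene, left_x=left, right_x=right, time_h=scene.time_h + dt_h)


def ground_truth_edge(scene: SceneState, which_front: str = "left") -> Polyline:
    """Exact sub-pixel polyline of one wound front, ordered top-to-bottom.

    Evaluation oracle only -- the edge detector never sees it.
    """
    if which_front not in ("left", "right"):
        raise ValueError("which_front must be 'left' or 'right'")
    if scene.is_closed:
        raise WoundClosedError("no wound: the scratch has fully closed")
    front = scene.left_x if which_front == "left" else scene.right_x
    rows = np.arange(len(front), dtype=float)
    if scene.params.orientation == "vertical":
        verts = np.column_stack([front, rows])
    else:
        verts = np.column_stack([rows, front])
    return Polyline(verts, frame="camera")


def ground_truth_edges(scene: SceneState) -> tuple[Polyline, Polyline]:
    """Both wound fronts (left/top first)."""
    return ground_truth_edge(scene, "left"), ground_truth_edge(scene, "right")


# ---------------------------------------------------------------------------
# bench front-ends
# ---------------------------------------------------------------------------

class VirtualBench:
    """Capture interface over a :class:`BenchModel` and optional scene.

    ``capture(pattern)`` renders what the camera would see with the given
    projector pattern (``None`` = projector dark).  ``advance`` steps the
    mounted scene through simulated time; a real-hardware adapter would
    sleep instead -- callers never assume which.
    """

    def __init__(self, model: BenchModel, scene: SceneState | None = None):
        self.model = model
        self.scene = scene
        self._captures = 0

    @property
    def camera(self) -> FrameSpec:
        return self.model.camera

    @property
    def projector(self) -> FrameSpec:
        return self.model.projector

    def reseed(self, seed: int) -> None:
        self.model.rng_seed = int(seed)
        self._captures = 0

    def capture(self, pattern: np.ndarray | None = None) -> np.ndarray:
        if pattern is not None and pattern.dtype == bool:
            pattern = pattern.astype(np.float32) * 255.0
        img = render_camera_view(
            self.model, pattern, self.scene, noise_index=self._captures
        )
        self._captures += 1
        return img

    def advance(self, dt_h: float, illumination: np.ndarray | None = None) -> None:
        if self.scene is not None and dt_h > 0:
            self.scene = step_scene(self.scene, dt_h, illumination)

    def project_to_camera(self, pattern: np.ndarray) -> np.ndarray:
        """Camera-frame boolean mask of where a pattern's light lands
        (ground-truth warp + footprint) -- what the sample receives."""
        pat = np.asarray(pattern)
        if pat.dtype != bool:
            pat = pat > 0
        warped = self.model._warp_to_camera(pat.astype(float)) >= 0.5
        return warped & self.model.footprint()


class FolderBench:
    """Offline bench for real hardware captures.

    Each requested pattern is written to ``<root>/patterns/pattern_NNNN.png``
    and the correspondingly named capture is read back from
    ``<root>/captures/capture_NNNN.png`` (``pattern=None`` writes an all-off
    frame).  Run once against hardware to produce the captures, then replay.
    """

    def __init__(self, root, camera: FrameSpec = CAMERA_FRAME,
                 projector: FrameSpec = PROJECTOR_FRAME):
        import pathlib

        self.root = pathlib.Path(root)
        self.camera = camera
        self.projector = projector
        self._index = 0
        (self.root / "patterns").mkdir(parents=True, exist_ok=True)

    def capture(self, pattern: np.ndarray | None = None) -> np.ndarray:
        import imageio.v3 as iio

        if pattern is None:
            pattern = np.zeros(self.projector.shape, dtype=np.uint8)
        if pattern.dtype == bool:
            pattern = pattern.astype(np.uint8) * 255
        name = f"{self._index:04d}"
        iio.imwrite(self.root / "patterns" / f"pattern_{name}.png",
                    np.asarray(pattern, dtype=np.uint8))
        cap = self.root / "captures" / f"capture_{name}.png"
        self._index += 1
        if not cap.exists():
            raise BenchError(
                f"missing capture {cap}: project the written patterns on the "
                "hardware, save the camera images under captures/, and rerun"
            )
        img = iio.imread(cap)
        if img.ndim == 3:
            img = img[..., :3].mean(axis=2)
        return np.asarray(img, dtype=np.uint8)


def random_bench(
    seed: int,
    camera: FrameSpec = FrameSpec(384, 216, "camera"),
    rotation_max_deg: float = 10.0,
    scale_range: tuple[float, float] = (0.5, 2.0),
    translation_frac: float = 0.25,
    noise_sigma_max: float = 4.0,
    blur_sigma_max: float = 2.0,
    coverage_margin: float = 1.6,
    background_level: float = 20.0,
) -> BenchModel:
    """Sample a random bench configuration.

    The ground-truth projector->camera map is a similarity with rotation
    uniform in +-``rotation_max_deg``, scale log-uniform over
    ``scale_range`` and translation uniform within
    +-``translation_frac`` of the camera frame; blur and noise are uniform
    up to their maxima.  The projector frame is sized so its footprint
    covers the whole camera frame even at the largest translation
    (real setups aim the projector to cover the full field of view).
    """
    rng = np.random.default_rng(seed)
    rot = rng.uniform(-rotation_max_deg, rotation_max_deg)
    lo, hi = scale_range
    scale = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    tx = rng.uniform(-translation_frac, translation_frac) * camera.width
    ty = rng.uniform(-translation_frac, translation_frac) * camera.height
    pw = int(math.ceil(camera.width * coverage_margin / scale))
    ph = int(math.ceil(camera.height * coverage_margin / scale))
    projector = FrameSpec(pw, ph, "projector")
    th = math.radians(rot)
    lin = scale * np.array(
        [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
    )
    cam_c = np.asarray(camera.center)
    proj_c = np.asarray(projector.center)
    t = cam_c + np.array([tx, ty]) - lin @ proj_c
    gt = AffineMap.from_linear(lin, tuple(t), source="projector", target="camera")
    return BenchModel(
        ground_truth_map=gt,
        camera=camera,
        projector=projector,
        blur_sigma=float(rng.uniform(0.0, blur_sigma_max)),
        noise_sigma=float(rng.uniform(0.0, noise_sigma_max)),
        background_level=background_level,
        rng_seed=int(rng.integers(2**31)),
    )
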