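"""Projector-camera calibration by banded structured-light scanning.

The procedure recovers the camera -> projector affine transform without any
prior knowledge of the optical arrangement:

1. flood-illuminate the projector frame and threshold the camera difference
   image (lit minus dark) to find the *illuminable region*;
2. sweep bands of adjacent projector columns, recording the mean intensity
   inside each camera-frame *scan zone*;
3. repeat for rows;
4. localise each zone's projector-frame position from the column/row bands
   with the highest responses;
5. fit a least-squares affine transform to the (camera centre, projector
   position) correspondences.

Hyper-parameters adapt to the (unknown) optical magnification ``M``: the
camera-frame breadth of a projected scan line of ``l_p`` projector pixels is
``l_c = M * l_p``, and a scan zone must be wide enough for at least two scan
lines to cross it, so ``s_c ~= 2 * l_c``.  ``M`` itself is estimated before
calibration by comparing a projected grid against a reference grid of known
camera spacing: with grid spacings ``G_p`` (projector px) and ``G_c``
(camera px) and observed square sizes ``g_p`` and ``g_c`` (any common unit),

    M = (g_c * G_p) / (G_c * g_p)

which combines with the relations above into the single sizing rule
``s_c ~= 2 * l_p * g_c * G_p / (G_c * g_p)``.  Note the symbol convention:
``g_c`` is the *projected* grid square's observed size and ``g_p`` the
reference square's; the automatic grid measurement feeds the detected
projected-grid pitch as ``g_c`` with ``g_p = G_c``.

Scan zones are spread toward the corners of the illuminable region's
bounding box under a border variable ``b`` in [0, 1]: at ``b = 0`` the
centres sit on the border (maximal leverage for the affine fit, but close
to stray-light artefacts); at ``b = 1`` the zones pack mutually adjacent
around the centre.  ``b = 1/3`` is a good compromise in practice.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.measure import label

from .geometry import AffineMap, FrameSpec

__all__ = [
    "CalibrationError",
    "CalibrationParams",
    "IlluminableRegion",
    "ScanZone",
    "ScanProfile",
    "CalibrationResult",
    "detect_illuminable_region",
    "estimate_magnification",
    "scan_zone_breadth",
    "scan_zone_breadth_raw",
    "scan_zone_breadth_combined",
    "scan_zone_breadth_combined_raw",
    "place_scan_zones",
    "run_axis_scan",
    "estimate_zone_positions",
    "measure_grid_magnification",
    "grid_pattern",
    "fit_affine",
    "calibrate",
    "region_feedback_image",
]


class CalibrationError(RuntimeError):
    """Calibration failure, tagged with the pipeline stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class CalibrationParams:
    """User-facing knobs plus the quantities derived from them.

    ``brightness``/``threshold`` control illuminable-region detection;
    ``b`` places the scan zones; ``l_p`` is the projector-frame scan-line
    breadth (smaller is more accurate but needs more captures).  ``M``,
    ``l_c`` and ``s_c`` are filled in during calibration unless supplied.
    """

    brightness: float = 200.0        # projector drive level, [0, 255]
    threshold: float = 50.0          # camera difference cutoff, [0, 255]
    b: float = 1.0 / 3.0             # border variable, [0, 1]
    l_p: int = 10                    # scan-line breadth, projector px
    n_zones: int = 4
    G_p: float | None = None         # projected grid spacing, projector px
    G_c: float | None = None         # reference grid spacing, camera px
    g_p: float | None = None         # observed reference-square size
    g_c: float | None = None         # observed projected-square size
    M: float | None = None           # magnification (derived if None)
    l_c: float | None = None         # scan-line breadth, camera px (derived)
    s_c: int | None = None           # scan-zone breadth, camera px (derived)
    peak_mode: str = "halfmass"      # "halfmass" | "centroid" | "argmax"
    peak_floor_frac: float = 0.02    # bands below this fraction of peak ignored
    contrast_floor: float | None = None  # absolute; default 5x dark-frame MAD
    residual_warn: float = 3.0       # projector px

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0):
            raise ValueError("border variable b must be in [0, 1]")
        if self.l_p < 1:
            raise ValueError("l_p must be >= 1")
        if not (0.0 < self.brightness <= 255.0):
            raise ValueError("brightness must be in (0, 255]")
        if not (0.0 <= self.threshold <= 255.0):
            raise ValueError("threshold must be in [0, 255]")
        if self.n_zones not in (3, 4):
            raise ValueError("n_zones must be 3 or 4")
        if self.peak_mode not in ("halfmass", "centroid", "argmax"):
            raise ValueError("peak_mode must be 'halfmass', 'centroid' or 'argmax'")


@dataclass(frozen=True, eq=False)
class IlluminableRegion:
    """Camera pixels the projector can light, plus bounding box and area."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), inclusive
    area: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "IlluminableRegion":
        ys, xs = np.nonzero(mask)
        if not len(xs):
            raise ValueError("empty mask")
        return cls(
            mask=mask.astype(bool),
            bbox=(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())),
            area=int(len(xs)),
        )


@dataclass(frozen=True)
class ScanZone:
    """Square camera-frame zone in which scan intensities are measured."""

    centre: tuple[float, float]
    breadth: int

    def slices(self, frame: FrameSpec) -> tuple[slice, slice]:
        half = self.breadth // 2
        cx, cy = int(round(self.centre[0])), int(round(self.centre[1]))
        return (
            slice(max(cy - half, 0), min(cy + half + 1, frame.height)),
            slice(max(cx - half, 0), min(cx + half + 1, frame.width)),
        )

    def measured_centre(self, frame: FrameSpec) -> tuple[float, float]:
        """Centre of the pixel square actually averaged over (the nominal
        centre rounded to the grid, adjusted for frame clipping)."""
        ys, xs = self.slices(frame)
        return ((xs.start + xs.stop - 1) / 2.0, (ys.start + ys.stop - 1) / 2.0)


@dataclass(frozen=True, eq=False)
class ScanProfile:
    """Per-zone intensity responses for one scan axis."""

    axis: str                  # "columns" | "rows"
    band_breadth: int          # l_p
    intensities: np.ndarray    # (n_zones, n_bands)
    dark_noise_mad: float      # robust noise scale of the dark frame

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[1]


@dataclass
class CalibrationResult:
    """Fitted camera->projector map plus fit diagnostics."""

    map: AffineMap
    residual: float                                   # RMS, projector px
    correspondences: list[tuple[tuple[float, float], tuple[float, float]]]
    params_used: CalibrationParams | None = None

    def to_dict(self) -> dict:
        d = {
            "map": self.map.to_dict(),
            "residual": self.residual,
            "correspondences": [
                {"camera": list(c), "projector": list(p)}
                for c, p in self.correspondences
            ],
        }
        if self.params_used is not None:
            p = self.params_used
            d["params"] = {
                "brightness": p.brightness,
                "threshold": p.threshold,
                "b": p.b,
                "l_p": p.l_p,
                "n_zones": p.n_zones,
                "M": p.M,
                "l_c": p.l_c,
                "s_c": p.s_c,
                "peak_mode": p.peak_mode,
            }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            map=AffineMap.from_dict(d["map"]),
            residual=float(d["residual"]),
            correspondences=[
                (tuple(c["camera"]), tuple(c["projector"]))
                for c in d.get("correspondences", [])
            ],
        )


# ---------------------------------------------------------------------------
# step 1: illuminable region
# ---------------------------------------------------------------------------

def detect_illuminable_region(
    bench, brightness: float, threshold: float
) -> IlluminableRegion:
    """Flood-illuminate the projector and threshold the difference image.

    The dark frame (projector fully off) is subtracted first so the
    threshold refers to projector light only, independent of the scene.
    Only the largest connected component is kept, rejecting stray-light
    specks near the borders.
    """
    if brightness <= 0:
        raise CalibrationError("detect_illuminable_region", "brightness must be > 0")
    if not (0 <= threshold <= 255):
        raise CalibrationError(
            "detect_illuminable_region", "threshold must be in [0, 255]"
        )
    dark = bench.capture(None).astype(float)
    lit = bench.capture(
        np.full(bench.projector.shape, brightness, dtype=np.float32)
    ).astype(float)
    diff = lit - dark
    raw = diff >= threshold
    if not raw.any():
        raise CalibrationError(
            "detect_illuminable_region",
            f"no illuminable region at threshold {threshold:g}; "
            f"max observed difference was {diff.max():.1f}",
        )
    lab = label(raw, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == int(np.argmax(counts))
    return IlluminableRegion.from_mask(mask)


# ---------------------------------------------------------------------------
# hyper-parameter sizing (magnification and scan-zone breadth)
# ---------------------------------------------------------------------------

def estimate_magnification(G_p: float, g_p: float, G_c: float, g_c: float) -> float:
    """Magnification from relative grid-square sizes: M = g_c*G_p / (G_c*g_p)."""
    for name, v in (("G_p", G_p), ("g_p", g_p), ("G_c", G_c), ("g_c", g_c)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (g_c * G_p) / (G_c * g_p)


def _round_up_odd(x: float) -> int:
    s = int(math.ceil(x - 1e-9))
    if s % 2 == 0:
        s += 1
    return max(s, 1)


def scan_zone_breadth_raw(l_p: float, M: float) -> float:
    """Unrounded scan-zone breadth: s_c = 2 * M * l_p (camera px)."""
    if l_p < 1:
        raise ValueError("l_p must be >= 1")
    if M <= 0:
        raise ValueError("M must be positive")
    return 2.0 * M * l_p


def scan_zone_breadth(l_p: float, M: float) -> int:
    """Scan-zone breadth rounded up to the next odd integer >= 1, so a zone
    has a well-defined centre pixel."""
    return _round_up_odd(scan_zone_breadth_raw(l_p, M))


def scan_zone_breadth_combined_raw(
    l_p: float, G_p: float, g_p: float, G_c: float, g_c: float
) -> float:
    """One-shot sizing rule: s_c = 2 * l_p * g_c * G_p / (G_c * g_p)."""
    if l_p < 1:
        raise ValueError("l_p must be >= 1")
    for name, v in (("G_p", G_p), ("g_p", g_p), ("G_c", G_c), ("g_c", g_c)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return 2.0 * l_p * g_c * G_p / (G_c * g_p)


def scan_zone_breadth_combined(
    l_p: float, G_p: float, g_p: float, G_c: float, g_c: float
) -> int:
    return _round_up_odd(scan_zone_breadth_combined_raw(l_p, G_p, g_p, G_c, g_c))


# ---------------------------------------------------------------------------
# step 1b: scan-zone placement
# ---------------------------------------------------------------------------

_CORNER_DIRS = ((-1, -1), (1, -1), (-1, 1), (1, 1))


def place_scan_zones(
    region: IlluminableRegion, b: float, s_c: int, n_zones: int = 4
) -> list[ScanZone]:
    """Spread scan zones toward the bounding-box corners of the region.

    Per-axis offset from the bbox centre is ``(1 - b) * h + b * s_c / 2``
    where ``h`` is the bbox half-extent: at ``b = 0`` the centres lie on the
    bbox border, at ``b = 1`` the zones pack mutually adjacent around the
    centre.  A zone whose square is not fully inside the mask is nudged
    toward the centre until it is (or at least until it intersects the
    mask); if no placement works the region is too small.
    """
    if not (0.0 <= b <= 1.0):
        raise CalibrationError("place_scan_zones", "b must be in [0, 1]")
    if n_zones not in (3, 4):
        raise CalibrationError("place_scan_zones", "n_zones must be 3 or 4")
    if s_c < 1:
        raise CalibrationError("place_scan_zones", "s_c must be >= 1")
    x0, y0, x1, y1 = region.bbox
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    hx, hy = (x1 - x0) / 2.0, (y1 - y0) / 2.0
    off_x = (1.0 - b) * hx + b * (s_c / 2.0)
    off_y = (1.0 - b) * hy + b * (s_c / 2.0)

    mask = region.mask
    # zone intersects the mask <=> rounded centre inside the mask dilated
    # by the zone square
    touch = ndi.maximum_filter(mask, size=s_c, mode="constant", cval=False)

    def ok(m: np.ndarray, x: float, y: float) -> bool:
        ix, iy = int(round(x)), int(round(y))
        return (
            0 <= iy < m.shape[0] and 0 <= ix < m.shape[1] and bool(m[iy, ix])
        )

    zones: list[ScanZone] = []
    for dx, dy in _CORNER_DIRS[:n_zones]:
        x, y = cx + dx * off_x, cy + dy * off_y
        placed = None
        vec = np.array([cx - x, cy - y])
        dist = float(np.hypot(*vec))
        step = vec / dist if dist > 0 else np.zeros(2)
        for k in range(int(math.ceil(dist)) + 1):
            qx, qy = x + k * step[0], y + k * step[1]
            if ok(touch, qx, qy):
                placed = (qx, qy)
                break
        if placed is None:
            raise CalibrationError(
                "place_scan_zones",
                f"region too small to host a {s_c} px zone toward corner "
                f"({dx:+d},{dy:+d})",
            )
        zones.append(ScanZone(centre=placed, breadth=int(s_c)))
    for i in range(len(zones)):
        for j in range(i + 1, len(zones)):
            ddx = abs(zones[i].centre[0] - zones[j].centre[0])
            ddy = abs(zones[i].centre[1] - zones[j].centre[1])
            if ddx < s_c - 1e-6 and ddy < s_c - 1e-6:
                raise CalibrationError(
                    "place_scan_zones",
                    f"region too small to host {n_zones} disjoint "
                    f"{s_c} px zones",
                )
    return zones


# ---------------------------------------------------------------------------
# steps 2-3: banded scans
# ---------------------------------------------------------------------------

def _zone_mean(img: np.ndarray, zone: ScanZone, frame: FrameSpec) -> float:
    ys, xs = zone.slices(frame)
    return float(img[ys, xs].mean())


def run_axis_scan(
    bench, axis: str, l_p: int, zones: list[ScanZone], brightness: float = 200.0
) -> ScanProfile:
    """Sweep adjacent non-overlapping bands of ``l_p`` projector columns (or
    rows), recording each zone's dark-subtracted mean intensity per band.

    Bands tile the projector extent with stride ``l_p``; a final partial
    band is treated as a full band centred at ``(k + 0.5) * l_p``.
    """
    if axis not in ("columns", "rows"):
        raise CalibrationError("run_axis_scan", "axis must be 'columns' or 'rows'")
    if l_p < 1:
        raise CalibrationError("run_axis_scan", "l_p must be >= 1")
    proj = bench.projector
    extent = proj.width if axis == "columns" else proj.height
    n_bands = int(math.ceil(extent / l_p))
    dark = bench.capture(None).astype(float)
    med = np.median(dark)
    dark_mad = float(np.median(np.abs(dark - med))) * 1.4826
    cam = bench.camera
    dark_means = np.array([_zone_mean(dark, z, cam) for z in zones])
    intensities = np.zeros((len(zones), n_bands))
    for k in range(n_bands):
        pattern = np.zeros(proj.shape, dtype=np.float32)
        lo, hi = k * l_p, min((k + 1) * l_p, extent)
        if axis == "columns":
            pattern[:, lo:hi] = brightness
        else:
            pattern[lo:hi, :] = brightness
        try:
            img = bench.capture(pattern).astype(float)
        except Exception as exc:  # annotate which band failed
            raise CalibrationError(
                "run_axis_scan", f"capture failed at {axis} band {k}: {exc}"
            ) from exc
        for z, zone in enumerate(zones):
            intensities[z, k] = _zone_mean(img, zone, cam) - dark_means[z]
    return ScanProfile(
        axis=axis, band_breadth=int(l_p), intensities=intensities,
        dark_noise_mad=dark_mad,
    )


# ---------------------------------------------------------------------------
# step 4: projector-frame zone positions
# ---------------------------------------------------------------------------

def _band_centre(k, l_p: int):
    """Mean pixel-centre coordinate of band k (columns k*l_p .. k*l_p+l_p-1)."""
    return k * l_p + (l_p - 1) / 2.0


def _profile_position(
    I: np.ndarray, l_p: int, mode: str, floor_frac: float
) -> float:
    I = np.clip(np.asarray(I, dtype=float), 0.0, None)
    peak = I.max()
    if mode == "argmax":
        k = int(np.argmax(I))  # ties break toward the lower band index
        return float(_band_centre(k, l_p))
    sel = I >= max(floor_frac, 1e-12) * peak
    if mode == "centroid":
        idx = np.nonzero(sel)[0]
        centres = _band_centre(idx.astype(float), l_p)
        return float(np.sum(I[idx] * centres) / np.sum(I[idx]))
    # half-mass: spread each band's response uniformly over its pixel extent
    # [k*l_p - 0.5, (k+1)*l_p - 0.5) and take the interpolated median of the
    # resulting density.  Exact for any box-shaped aperture response,
    # whatever its width or phase relative to the band grid.
    w = np.where(sel, I, 0.0)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    half = cum[-1] / 2.0
    j = int(np.searchsorted(cum, half, side="right")) - 1
    j = min(max(j, 0), len(I) - 1)
    while w[j] == 0.0 and j < len(I) - 1:
        j += 1
    left_edge = j * l_p - 0.5
    return float(left_edge + (half - cum[j]) / w[j] * l_p)


def estimate_zone_positions(
    col_profile: ScanProfile,
    row_profile: ScanProfile,
    l_p: int | None = None,
    mode: str = "halfmass",
    contrast_floor: float | None = None,
    peak_floor_frac: float = 0.02,
) -> tuple[list[tuple[float, float]], list[int]]:
    """Projector-frame (x, y) of each zone from its peak scan responses.

    Positions are in pixel-centre coordinates (band ``k`` spans columns
    ``k*l_p .. k*l_p + l_p - 1``, central coordinate ``k*l_p + (l_p-1)/2``).
    The default ``halfmass`` localiser takes the interpolated half-mass
    point of the band responses, which is exact for a box-shaped zone
    aperture of any width or phase; ``centroid`` is the intensity-weighted
    mean of band centres, and ``argmax`` the bare highest band with ties
    broken toward the lower index.  Bands below ``peak_floor_frac`` of the
    zone's peak are ignored as noise.  Zones whose peak response does not
    clear the contrast floor (default 5x the dark-frame noise MAD) are
    excluded with a warning; losing so many that fewer than three remain
    is an error.

    Returns the positions and the indices of the zones that were kept.
    """
    if l_p is None:
        l_p = col_profile.band_breadth
    if col_profile.intensities.shape[0] != row_profile.intensities.shape[0]:
        raise CalibrationError(
            "estimate_zone_positions", "column/row profiles disagree on zone count"
        )
    if contrast_floor is None:
        contrast_floor = 5.0 * max(
            col_profile.dark_noise_mad, row_profile.dark_noise_mad
        )
    positions: list[tuple[float, float]] = []
    kept: list[int] = []
    n = col_profile.intensities.shape[0]
    for z in range(n):
        ci = np.clip(col_profile.intensities[z], 0.0, None)
        ri = np.clip(row_profile.intensities[z], 0.0, None)
        if ci.max() <= contrast_floor or ri.max() <= contrast_floor:
            warnings.warn(
                f"scan zone {z} excluded: peak contrast below floor "
                f"({contrast_floor:.2f})",
                stacklevel=2,
            )
            continue
        x = _profile_position(ci, l_p, mode, peak_floor_frac)
        y = _profile_position(ri, l_p, mode, peak_floor_frac)
        positions.append((x, y))
        kept.append(z)
    required = min(3, n)
    if len(positions) < required:
        raise CalibrationError(
            "estimate_zone_positions",
            f"only {len(positions)} of {n} scan zones usable (need >= {required})",
        )
    return positions, kept


# ---------------------------------------------------------------------------
# grid-based magnification measurement
# ---------------------------------------------------------------------------

def grid_pattern(
    frame: FrameSpec, spacing: int, line_px: int = 3, level: float = 200.0
) -> np.ndarray:
    """Projector grid: vertical + horizontal lines every ``spacing`` px."""
    if spacing < 2:
        raise ValueError("grid spacing must be >= 2")
    pat = np.zeros(frame.shape, dtype=np.float32)
    for x0 in range(0, frame.width, spacing):
        pat[:, x0 : x0 + line_px] = level
    for y0 in range(0, frame.height, spacing):
        pat[y0 : y0 + line_px, :] = level
    return pat


def _dominant_pitch(img: np.ndarray, min_r: float = 4.0) -> float | None:
    """Pitch of a periodic lattice via the nearest autocorrelation side peak."""
    img = np.asarray(img, dtype=float)
    img = img - img.mean()
    if img.std() < 1e-6 or min(img.shape) < 8:
        return None
    ac = fftconvolve(img, img[::-1, ::-1], mode="same")
    cy, cx = np.array(ac.shape) // 2
    peak0 = ac[cy, cx]
    if peak0 <= 0:
        return None
    # true lattice side peaks carry most of the zero-lag energy; weak
    # near-origin maxima from noise/line-thickness ripple stay well below
    local_max = ac == ndi.maximum_filter(ac, size=5, mode="nearest")
    ys, xs = np.nonzero(local_max & (ac > 0.45 * peak0))
    r = np.hypot(xs - cx, ys - cy)
    r = r[r > min_r]
    if not len(r):
        return None
    return float(r.min())


def measure_grid_magnification(
    bench,
    region: IlluminableRegion,
    brightness: float = 200.0,
    G_p: int | None = None,
    G_c: int | None = None,
) -> tuple[float, float]:
    """Estimate M by projecting a grid and measuring its pitch on camera.

    The reference grid is the camera's own pixel lattice at spacing ``G_c``
    (observed size exactly ``G_c`` camera px), so the measured projected
    pitch enters the magnification relation as ``g_c`` with ``g_p = G_c``.
    Falls back to a footprint-area estimate
    ``sqrt(region area / projector area)`` when no reliable pitch is found.

    Returns ``(M, measured_pitch_or_nan)``.
    """
    proj = bench.projector
    if G_p is None:
        G_p = max(8, round(min(proj.width, proj.height) / 8))
    if G_c is None:
        G_c = G_p
    area_est = math.sqrt(region.area / (proj.width * proj.height))
    dark = bench.capture(None).astype(float)
    img = bench.capture(grid_pattern(proj, int(G_p), level=brightness)).astype(float)
    diff = img - dark
    x0, y0, x1, y1 = region.bbox
    # crop the bbox interior so the footprint boundary does not dominate
    mx = max(1, (x1 - x0) // 10)
    my = max(1, (y1 - y0) // 10)
    crop = diff[y0 + my : y1 - my + 1, x0 + mx : x1 - mx + 1]
    pitch = _dominant_pitch(crop)
    if pitch is not None:
        M = estimate_magnification(G_p=G_p, g_p=G_c, G_c=G_c, g_c=pitch)
        if area_est > 0 and not (0.4 < M / area_est < 2.5):
            warnings.warn(
                f"grid magnification {M:.3g} disagrees with footprint-area "
                f"estimate {area_est:.3g}; using the area estimate",
                stacklevel=2,
            )
            return area_est, float("nan")
        return M, pitch
    warnings.warn(
        "no grid pitch detected; using footprint-area magnification estimate",
        stacklevel=2,
    )
    return area_est, float("nan")


# ---------------------------------------------------------------------------
# step 5: affine fit
# ---------------------------------------------------------------------------

def fit_affine(
    correspondences: list[tuple[tuple[float, float], tuple[float, float]]],
) -> CalibrationResult:
    """Least-squares 6-parameter affine fit, camera -> projector.

    Exact (residual ~ 0) when the pairs are affine-consistent.  Fewer than
    three pairs, or collinear camera points, leave the transform
    under-determined and raise an error.
    """
    if len(correspondences) < 3:
        raise CalibrationError(
            "fit_affine",
            f"degenerate correspondence set: {len(correspondences)} pairs (need >= 3)",
        )
    src = np.array([c for c, _ in correspondences], dtype=float)
    dst = np.array([p for _, p in correspondences], dtype=float)
    centred = src - src.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise CalibrationError(
            "fit_affine", "degenerate correspondence set: camera points collinear"
        )
    A = np.column_stack([src, np.ones(len(src))])
    sol, *_ = np.linalg.lstsq(A, dst, rcond=None)
    matrix = sol.T
    pred = A @ sol
    residual = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    return CalibrationResult(
        map=AffineMap(matrix, source="camera", target="projector"),
        residual=residual,
        correspondences=[
            (tuple(map(float, c)), tuple(map(float, p)))
            for c, p in zip(src, dst)
        ],
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def calibrate(
    bench,
    params: CalibrationParams | None = None,
    interactive: bool = False,
    input_fn=input,
    echo=print,
) -> CalibrationResult:
    """Run the full calibration pipeline against any bench backend.

    In batch mode (default) every value comes from ``params``; the
    magnification is taken from ``params.M`` if set, computed from the
    user-reported grid sizes if all of ``G_p, g_p, G_c, g_c`` are set, and
    otherwise measured automatically by projecting a grid.  In interactive
    mode the user is prompted for brightness, threshold and the grid
    observations, with textual feedback after region detection.
    """
    p = params or CalibrationParams()
    if interactive:
        return _calibrate_interactive(bench, p, input_fn, echo)
    region = detect_illuminable_region(bench, p.brightness, p.threshold)
    M = p.M
    if M is None and None not in (p.G_p, p.g_p, p.G_c, p.g_c):
        M = estimate_magnification(p.G_p, p.g_p, p.G_c, p.g_c)
    if M is None:
        M, _ = measure_grid_magnification(
            bench, region, p.brightness,
            int(p.G_p) if p.G_p else None, int(p.G_c) if p.G_c else None,
        )
    s_c = p.s_c if p.s_c is not None else scan_zone_breadth(p.l_p, M)
    zones = place_scan_zones(region, p.b, s_c, p.n_zones)
    cols = run_axis_scan(bench, "columns", p.l_p, zones, p.brightness)
    rows = run_axis_scan(bench, "rows", p.l_p, zones, p.brightness)
    positions, kept = estimate_zone_positions(
        cols, rows, p.l_p, p.peak_mode, p.contrast_floor, p.peak_floor_frac
    )
    pairs = [
        (zones[i].measured_centre(bench.camera), pos)
        for i, pos in zip(kept, positions)
    ]
    result = fit_affine(pairs)
    result.params_used = replace(p, M=M, l_c=M * p.l_p, s_c=int(s_c))
    if result.residual > p.residual_warn:
        warnings.warn(
            f"calibration residual {result.residual:.2f} projector px exceeds "
            f"{p.residual_warn:g}; inspect the scan profiles",
            stacklevel=2,
        )
    return result


def region_feedback_image(
    region: IlluminableRegion, zones: list[ScanZone] | None = None
) -> np.ndarray:
    """RGB feedback image: illuminable region in white, proposed scan-zone
    centres as red markers (marker size is not the zone size)."""
    h, w = region.mask.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[region.mask] = 255
    if zones:
        for z in zones:
            cx, cy = int(round(z.centre[0])), int(round(z.centre[1]))
            y0, y1 = max(cy - 3, 0), min(cy + 4, h)
            x0, x1 = max(cx - 3, 0), min(cx + 4, w)
            img[y0:y1, x0:x1] = (255, 0, 0)
    return img


def _calibrate_interactive(bench, p: CalibrationParams, input_fn, echo):
    """Thin prompt layer over the batch pipeline (kept headless-testable)."""

    def ask(prompt: str, default, cast=float):
        raw = input_fn(f"{prompt} [{default}]: ").strip()
        return cast(raw) if raw else default

    while True:
        p.brightness = ask("projector brightness (0-255)", p.brightness)
        p.threshold = ask("detection threshold (0-255)", p.threshold)
        try:
            region = detect_illuminable_region(bench, p.brightness, p.threshold)
        except CalibrationError as exc:
            echo(str(exc))
            continue
        x0, y0, x1, y1 = region.bbox
        echo(
            f"illuminable region: {region.area} px, "
            f"bbox ({x0},{y0})-({x1},{y1})"
        )
        if input_fn("accept region? [Y/n]: ").strip().lower() not in ("n", "no"):
            break
    p.b = ask("border variable b (0-1)", p.b)
    p.l_p = ask("scan-line breadth l_p (projector px)", p.l_p, int)
    if input_fn("enter grid observations for M? [y/N]: ").strip().lower() in ("y", "yes"):
        p.G_p = ask("projected grid spacing G_p (projector px)", p.G_p or 32)
        p.G_c = ask("reference grid spacing G_c (camera px)", p.G_c or 32)
        p.g_c = ask("observed projected-square size g_c", p.g_c or 1.0)
        p.g_p = ask("observed reference-square size g_p", p.g_p or 1.0)
        p.M = estimate_magnification(p.G_p, p.g_p, p.G_c, p.g_c)
        echo(f"magnification M = {p.M:.3f}")
    result = calibrate(bench, p, interactive=False)
    echo(
        f"calibration done: residual {result.residual:.3f} projector px over "
        f"{len(result.correspondences)} correspondences"
    )
    return result
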