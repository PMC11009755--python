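"""Brightfield image -> wound-edge polyline -> projector pattern.

The pipeline segments the monolayer from a single brightfield frame,
traces the boundary contours of the segmentation, discards contour parts
hugging the image border, keeps the longest remaining continuous chain as
the leading wound edge, and maps that chain through the camera->projector
calibration into a rasterised illumination pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import exposure, measure, morphology
from skimage.filters import threshold_otsu

from .geometry import AffineMap, FrameSpec, Polyline, rasterize_polyline

__all__ = [
    "TargetingError",
    "SegmentationSettings",
    "TargetingResult",
    "segment_monolayer",
    "extract_wound_edge",
    "edge_to_pattern",
    "target_wound",
]


class TargetingError(RuntimeError):
    """Targeting failure, tagged with the pipeline stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class SegmentationSettings:
    """Knobs of the segmentation step.

    ``polarity`` says which side of the threshold is the monolayer:
    ``"dark"`` (confluent sheets usually image darker than the cell-free
    scratch), ``"bright"``, or ``"auto"`` which picks the larger region --
    sensible whenever the wound is narrower than the surrounding sheet.
    """

    contrast_method: str = "stretch"        # "stretch" | "clahe"
    stretch_percentiles: tuple[float, float] = (2.0, 98.0)
    clahe_clip: float = 0.01
    threshold_method: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float = 128.0
    polarity: str = "auto"                  # "auto" | "dark" | "bright"
    min_object_px: int = 64
    closing_radius: int = 2
    edge_margin_px: int = 8

    def __post_init__(self) -> None:
        if self.contrast_method not in ("stretch", "clahe"):
            raise ValueError("contrast_method must be 'stretch' or 'clahe'")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.polarity not in ("auto", "dark", "bright"):
            raise ValueError("polarity must be 'auto', 'dark' or 'bright'")
        if not (0.0 <= self.fixed_threshold <= 255.0):
            raise ValueError("fixed_threshold must be in [0, 255]")
        if self.min_object_px < 0 or self.closing_radius < 0 or self.edge_margin_px < 0:
            raise ValueError("size parameters must be >= 0")


@dataclass
class TargetingResult:
    """All artefacts of one targeting pass, for logging and inspection."""

    mask: np.ndarray                 # monolayer segmentation, bool
    edge: Polyline                   # detected wound edge, camera frame
    pattern: np.ndarray              # projector-frame illumination, bool
    edge_length_px: float
    mapped_edge: Polyline | None = None  # edge in projector coordinates


def segment_monolayer(
    image: np.ndarray, settings: SegmentationSettings | None = None
) -> np.ndarray:
    """Contrast-enhance, threshold and clean a brightfield frame.

    With a fixed threshold the cutoff applies to the raw 8-bit intensities;
    Otsu operates on the contrast-enhanced image.  Morphological closing and
    small-object/hole removal regularise the mask.  An all-foreground or
    all-background result is degenerate (no wound to find).
    """
    s = settings or SegmentationSettings()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise TargetingError("segment_monolayer", "expected a 2-D grayscale image")
    if s.threshold_method == "fixed":
        work, thr = img, s.fixed_threshold
    else:
        if s.contrast_method == "stretch":
            lo, hi = np.percentile(img, s.stretch_percentiles)
            work = exposure.rescale_intensity(
                img, in_range=(lo, hi if hi > lo else lo + 1), out_range=(0.0, 255.0)
            )
        else:
            work = 255.0 * exposure.equalize_adapthist(
                np.clip(img, 0, 255).astype(np.uint8), clip_limit=s.clahe_clip
            )
        if work.std() < 1e-9:
            raise TargetingError(
                "segment_monolayer", "degenerate segmentation: uniform image"
            )
        thr = float(threshold_otsu(work))
    below = work < thr
    if s.polarity == "dark":
        mask = below
    elif s.polarity == "bright":
        mask = ~below
    else:
        mask = below if below.sum() >= below.size - below.sum() else ~below
    if s.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(s.closing_radius))
    if s.min_object_px > 0:
        mask = morphology.remove_small_objects(mask, max_size=s.min_object_px - 1)
        mask = morphology.remove_small_holes(mask, max_size=s.min_object_px - 1)
    if mask.all() or not mask.any():
        raise TargetingError(
            "segment_monolayer",
            "degenerate segmentation: mask is all foreground or all background",
        )
    return mask


def _contour_chains(mask: np.ndarray, margin: float) -> list[np.ndarray]:
    """Boundary chains of a mask with border-hugging parts removed.

    Contours are traced at the 0.5 level; points within ``margin`` px of
    the image border are discarded and each contour is split into maximal
    runs of surviving points.
    """
    h, w = mask.shape
    chains: list[np.ndarray] = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        xy = contour[:, ::-1]  # (row, col) -> (x, y)
        closed = len(xy) > 2 and np.allclose(xy[0], xy[-1])
        if closed:
            xy = xy[:-1]
        valid = (
            (xy[:, 0] >= margin)
            & (xy[:, 0] <= w - 1 - margin)
            & (xy[:, 1] >= margin)
            & (xy[:, 1] <= h - 1 - margin)
        )
        if not valid.any():
            continue
        if valid.all():
            chains.append(np.vstack([xy, xy[:1]]) if closed else xy)
            continue
        if closed:  # rotate so a discarded point sits at the seam
            first_bad = int(np.argmin(valid))
            xy = np.roll(xy, -first_bad, axis=0)
            valid = np.roll(valid, -first_bad)
        idx = np.nonzero(valid)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        for run in np.split(idx, breaks + 1):
            if len(run) >= 2:
                chains.append(xy[run])
    return chains


def extract_wound_edge(
    mask: np.ndarray,
    edge_margin_px: float = 8,
    return_all: bool = False,
):
    """Longest continuous boundary chain of the segmentation.

    Contour segments lying within ``edge_margin_px`` of the image border are
    discarded first, so the returned edge is never a frame-border artefact.
    With ``return_all=True`` every surviving chain is returned (longest
    first), e.g. to illuminate both wound fronts.
    """
    mask = np.asarray(mask, dtype=bool)
    chains = _contour_chains(mask, edge_margin_px)
    polys = sorted(
        (Polyline(c, frame="camera") for c in chains),
        key=lambda p: p.length,
        reverse=True,
    )
    polys = [p for p in polys if p.length > 0]
    if not polys:
        raise TargetingError(
            "extract_wound_edge",
            "no edge found: every contour lies within the border margin",
        )
    return polys if return_all else polys[0]


def edge_to_pattern(
    edge: Polyline,
    calib: AffineMap,
    projector: FrameSpec,
    thickness_pp: int = 5,
) -> np.ndarray:
    """Map a camera-frame edge into the projector and rasterise it.

    Returns a boolean projector-frame pattern of the edge drawn with
    ``thickness_pp`` projector-pixel line breadth, clipped to the frame.
    An edge mapping entirely outside the projector frame yields an all-off
    pattern with a warning; an empty edge is simply all-off.
    """
    if thickness_pp < 1:
        raise TargetingError("edge_to_pattern", "thickness must be >= 1")
    if len(edge) == 0:
        return np.zeros(projector.shape, dtype=bool)
    mapped = calib.apply(edge)
    pad = thickness_pp / 2.0
    v = mapped.vertices
    inside = (
        (v[:, 0] >= -0.5 - pad)
        & (v[:, 0] < projector.width - 0.5 + pad)
        & (v[:, 1] >= -0.5 - pad)
        & (v[:, 1] < projector.height - 0.5 + pad)
    )
    if not inside.any():
        warnings.warn(
            "wound edge maps entirely outside the projector frame", stacklevel=2
        )
        return np.zeros(projector.shape, dtype=bool)
    return rasterize_polyline(mapped, projector, thickness_pp)


def target_wound(
    image: np.ndarray,
    calib: AffineMap,
    projector: FrameSpec,
    settings: SegmentationSettings | None = None,
    thickness_pp: int = 5,
    front: str = "longest",
    prev_centroid: np.ndarray | None = None,
    simplify_tol: float = 0.5,
) -> TargetingResult:
    """Full targeting pass: segmentation -> edge -> projector pattern.

    ``front='longest'`` keeps the single longest chain (the leading edge);
    ``front='nearest'`` prefers, among chains at least half as long as the
    longest, the one whose centroid is closest to ``prev_centroid`` --
    used by the closed loop to keep following the same front between
    cycles.  The edge is simplified (tolerance ``simplify_tol`` px) before
    mapping, bounding the coordinate list sent to the projector.
    """
    s = settings or SegmentationSettings()
    mask = segment_monolayer(image, s)
    chains = extract_wound_edge(mask, s.edge_margin_px, return_all=True)
    edge = chains[0]
    if front == "nearest" and prev_centroid is not None and len(chains) > 1:
        cutoff = 0.5 * chains[0].length
        candidates = [c for c in chains if c.length >= cutoff]
        edge = min(
            candidates,
            key=lambda c: float(np.linalg.norm(c.centroid - prev_centroid)),
        )
    simplified = edge.simplify(simplify_tol)
    mapped = calib.apply(simplified)
    pattern = edge_to_pattern(simplified, calib, projector, thickness_pp)
    return TargetingResult(
        mask=mask,
        edge=edge,
        pattern=pattern,
        edge_length_px=edge.length,
        mapped_edge=mapped,
    )
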