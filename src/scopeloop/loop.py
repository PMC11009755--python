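"""Closed-loop scheduler: capture, re-detect the wound edge, re-project.

The loop engine interleaves periodic captures with periodic projections.
At each projection event the targeting pipeline is re-run on the latest
capture, so the projected pattern changes in line with the changes in the
sample.  On a virtual bench the mounted scene advances between events,
receiving as illumination the *actual* light field (the last pattern warped
through the ground-truth transform), and a per-projection tracking error
against the exact wound front is logged.

Simulated time is decoupled from wall-clock time: the virtual bench jumps
by schedule deltas, a hardware adapter would sleep.  The engine never
assumes which.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .bench import VirtualBench, ground_truth_edges
from .geometry import AffineMap, Polyline, rasterize_polyline
from .targeting import SegmentationSettings, TargetingError, target_wound

__all__ = [
    "LoopError",
    "LoopSchedule",
    "LoopEvent",
    "LoopLog",
    "build_schedule",
    "run_loop",
    "render_timelapse",
    "pattern_edge_distances",
    "tracking_correlation",
]

#: Overlay colours: detected edge in light blue, projected pattern in violet.
EDGE_COLOR = (80, 200, 255)
PATTERN_COLOR = (200, 80, 255)


class LoopError(RuntimeError):
    pass


@dataclass(frozen=True)
class LoopSchedule:
    """Explicit event timeline.  Timelines include t = 0 (capture and, by
    default, project immediately); an "every P for D" request therefore
    yields ``floor(D / P) + 1`` events."""

    imaging_period_min: float
    projection_period_min: float
    duration_h: float
    exposure_min: float
    project_at_start: bool = True

    @property
    def capture_times_min(self) -> list[float]:
        n = int(math.floor(self.duration_h * 60.0 / self.imaging_period_min + 1e-9))
        return [k * self.imaging_period_min for k in range(n + 1)]

    @property
    def projection_times_min(self) -> list[float]:
        n = int(math.floor(self.duration_h * 60.0 / self.projection_period_min + 1e-9))
        times = [k * self.projection_period_min for k in range(n + 1)]
        if not self.project_at_start:
            times = [t for t in times if t > 0]
        return times

    def events(self) -> list[tuple[float, str]]:
        """Chronological (time_min, kind) list; captures precede projections
        scheduled at the same instant, so each projection uses the frame
        just captured."""
        ev = [(t, "capture") for t in self.capture_times_min]
        ev += [(t, "project") for t in self.projection_times_min]
        ev.sort(key=lambda e: (e[0], 0 if e[1] == "capture" else 1))
        return ev


def build_schedule(
    imaging_period_min: float,
    projection_period_min: float,
    duration_h: float,
    exposure_min: float | None = None,
    project_at_start: bool = True,
) -> LoopSchedule:
    """Validate and build a loop schedule.

    The projection period must be an integer multiple of the imaging
    period, so every projection event coincides with a capture event.
    ``exposure_min`` is how long each projected pattern stays on; it
    defaults to the full projection period (continuous illumination
    between updates).
    """
    if imaging_period_min <= 0 or projection_period_min <= 0:
        raise LoopError("periods must be positive")
    if duration_h < 0:
        raise LoopError("duration must be >= 0")
    ratio = projection_period_min / imaging_period_min
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise LoopError(
            f"projection period ({projection_period_min} min) must be an integer "
            f"multiple of the imaging period ({imaging_period_min} min)"
        )
    if exposure_min is None:
        exposure_min = projection_period_min
    if not (0 < exposure_min <= projection_period_min):
        raise LoopError(
            "exposure_min must be in (0, projection_period_min]"
        )
    return LoopSchedule(
        imaging_period_min=float(imaging_period_min),
        projection_period_min=float(projection_period_min),
        duration_h=float(duration_h),
        exposure_min=float(exposure_min),
        project_at_start=project_at_start,
    )


@dataclass
class LoopEvent:
    """One capture or projection record."""

    index: int
    time_min: float
    kind: str                               # "capture" | "project"
    image: np.ndarray | None = None         # capture events
    source_capture: int | None = None       # projection events: capture index
    edge: Polyline | None = None
    pattern: np.ndarray | None = None       # projector-frame bool
    edge_length_px: float | None = None
    tracking_error: float | None = None     # mean px to true edge (virtual)
    tracking_distances: np.ndarray | None = None
    wound_area_px: float | None = None
    #: mean front positions along the wound normal (virtual bench only)
    gt_front_means: tuple[float, float] | None = None
    warning: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "index": self.index,
            "time_min": self.time_min,
            "kind": self.kind,
            "source_capture": self.source_capture,
            "edge_length_px": self.edge_length_px,
            "tracking_error": self.tracking_error,
            "wound_area_px": self.wound_area_px,
            "warning": self.warning,
        }


@dataclass
class LoopLog:
    """Chronological record of one closed-loop run."""

    events: list[LoopEvent] = field(default_factory=list)
    schedule: LoopSchedule | None = None

    def captures(self) -> list[LoopEvent]:
        return [e for e in self.events if e.kind == "capture"]

    def projections(self) -> list[LoopEvent]:
        return [e for e in self.events if e.kind == "project"]

    @property
    def final_wound_area_px(self) -> float | None:
        areas = [e.wound_area_px for e in self.captures() if e.wound_area_px is not None]
        return areas[-1] if areas else None

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e.to_json_dict()) + "\n")

    def equals(self, other: "LoopLog") -> bool:
        """Bitwise comparison of two runs (images, patterns, numbers)."""
        if len(self.events) != len(other.events):
            return False
        for a, b in zip(self.events, other.events):
            if (a.kind, a.time_min) != (b.kind, b.time_min):
                return False
            for x, y in ((a.image, b.image), (a.pattern, b.pattern)):
                if (x is None) != (y is None):
                    return False
                if x is not None and not np.array_equal(x, y):
                    return False
            if a.wound_area_px != b.wound_area_px:
                return False
            if a.tracking_error != b.tracking_error:
                return False
        return True


def pattern_edge_distances(
    pattern: np.ndarray, calib: AffineMap, scene
) -> np.ndarray:
    """Distance (camera px) from each back-mapped pattern on-pixel to the
    nearest true wound front."""
    ys, xs = np.nonzero(np.asarray(pattern, dtype=bool))
    if not len(xs):
        return np.array([])
    cam_pts = calib.inverse().apply(np.column_stack([xs, ys]).astype(float))
    left, right = ground_truth_edges(scene)
    gt = np.vstack([left.resample(1.0), right.resample(1.0)])
    tree = cKDTree(gt)
    d, _ = tree.query(cam_pts)
    return np.asarray(d)


def tracking_correlation(log: "LoopLog", calib: AffineMap) -> float:
    """Pearson correlation between the projected pattern's position and the
    true wound front's position across projection events.

    Both series are cumulative displacements along the wound normal (the
    x axis for a vertical wound band): the back-mapped pattern centroid on
    one side, the mean position of the tracked front (whichever true front
    the first pattern sits closer to) on the other.  Close to 1 when the
    pattern keeps following the moving edge.
    """
    by_index = {e.index: e for e in log.events}
    pat_x: list[float] = []
    front_pairs: list[tuple[float, float]] = []
    inv = calib.inverse()
    for e in log.projections():
        if e.pattern is None or e.source_capture is None:
            continue
        cap = by_index[e.source_capture]
        if cap.gt_front_means is None:
            continue
        ys, xs = np.nonzero(e.pattern)
        if not len(xs):
            continue
        centroid = inv.apply(np.array([[xs.mean(), ys.mean()]]))[0]
        pat_x.append(float(centroid[0]))
        front_pairs.append(cap.gt_front_means)
    if len(pat_x) < 3:
        raise LoopError("too few projections with ground truth to correlate")
    fp = np.array(front_pairs)
    tracked = int(np.argmin(np.abs(fp[0] - pat_x[0])))
    return float(np.corrcoef(pat_x, fp[:, tracked])[0, 1])


def run_loop(
    bench,
    calib: AffineMap,
    schedule: LoopSchedule,
    settings: SegmentationSettings | None = None,
    thickness_pp: int = 5,
    seed: int | None = None,
    outdir=None,
) -> LoopLog:
    """Execute a closed-loop run.

    At each capture event a brightfield frame is acquired (the projected
    pattern itself is not visible to the camera: the projection wavelength
    is blocked by the imaging filter).  At each projection event the
    targeting pipeline runs on the latest frame and the resulting pattern
    is projected for ``schedule.exposure_min``.  A failed edge detection
    logs a warning and re-projects the previous pattern; the loop never
    aborts.  On a virtual bench the scene advances between events under the
    light it actually received, and tracking errors against the exact wound
    front are recorded per projection.
    """
    if seed is not None and hasattr(bench, "reseed"):
        bench.reseed(seed)
    is_virtual = isinstance(bench, VirtualBench) and bench.scene is not None
    settings = settings or SegmentationSettings()
    log = LoopLog(schedule=schedule)
    t_prev = 0.0
    last_image: np.ndarray | None = None
    last_capture_idx: int | None = None
    last_pattern: np.ndarray | None = None
    light_mask: np.ndarray | None = None
    light_until = -math.inf
    prev_centroid: np.ndarray | None = None

    def advance_to(t: float) -> None:
        nonlocal t_prev
        while t - t_prev > 1e-9:
            if light_mask is not None and light_until - t_prev > 1e-9:
                t_seg = min(t, light_until)
                bench.advance((t_seg - t_prev) / 60.0, light_mask)
            else:
                t_seg = t
                bench.advance((t_seg - t_prev) / 60.0, None)
            t_prev = t_seg

    for i, (t, kind) in enumerate(schedule.events()):
        advance_to(t)
        if kind == "capture":
            img = bench.capture(None)
            last_image, last_capture_idx = img, i
            area = fronts = None
            if is_virtual:
                area = bench.scene.wound_area_px
                fronts = (
                    float(bench.scene.left_x.mean()),
                    float(bench.scene.right_x.mean()),
                )
            log.events.append(
                LoopEvent(index=i, time_min=t, kind="capture", image=img,
                          wound_area_px=area, gt_front_means=fronts)
            )
            continue
        # projection event
        if last_image is None:
            raise LoopError("projection scheduled before any capture")
        ev = LoopEvent(index=i, time_min=t, kind="project",
                       source_capture=last_capture_idx)
        try:
            res = target_wound(
                last_image, calib, bench.projector, settings, thickness_pp,
                front="nearest", prev_centroid=prev_centroid,
            )
            ev.edge = res.edge
            ev.pattern = res.pattern
            ev.edge_length_px = res.edge_length_px
            prev_centroid = res.edge.centroid
        except TargetingError as exc:
            msg = f"edge detection failed at t={t:g} min ({exc}); re-projecting previous pattern"
            warnings.warn(msg, stacklevel=2)
            ev.warning = msg
            ev.pattern = last_pattern
        if ev.pattern is not None:
            last_pattern = ev.pattern
            if is_virtual:
                light_mask = bench.project_to_camera(ev.pattern)
            light_until = t + schedule.exposure_min
            if is_virtual and not bench.scene.is_closed:
                d = pattern_edge_distances(ev.pattern, calib, bench.scene)
                if len(d):
                    ev.tracking_distances = d
                    ev.tracking_error = float(d.mean())
        log.events.append(ev)

    if outdir is not None:
        _write_outdir(log, outdir)
    return log


def _write_outdir(log: LoopLog, outdir) -> None:
    import pathlib

    import imageio.v3 as iio

    out = pathlib.Path(outdir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "patterns").mkdir(parents=True, exist_ok=True)
    for e in log.events:
        if e.kind == "capture" and e.image is not None:
            iio.imwrite(out / "frames" / f"frame_{e.index:04d}.png", e.image)
        elif e.kind == "project" and e.pattern is not None:
            iio.imwrite(
                out / "patterns" / f"pattern_{e.index:04d}.png",
                e.pattern.astype(np.uint8) * 255,
            )
    log.to_jsonl(out / "log.jsonl")
    areas = [e.wound_area_px for e in log.captures() if e.wound_area_px is not None]
    errs = [e.tracking_error for e in log.projections() if e.tracking_error is not None]
    summary = {
        "captures": len(log.captures()),
        "projections": len(log.projections()),
        "initial_wound_area_px": areas[0] if areas else None,
        "final_wound_area_px": areas[-1] if areas else None,
        "mean_tracking_error_px": float(np.mean(errs)) if errs else None,
        "warnings": sum(1 for e in log.events if e.warning),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def render_timelapse(
    log: LoopLog,
    calib: AffineMap | None = None,
    outdir=None,
    stack_path=None,
) -> np.ndarray:
    """Overlay time-lapse: one RGB frame per capture event.

    Each frame shows the brightfield capture with the most recent detected
    edge drawn in light blue and, when a calibration is supplied, the
    back-mapped projected pattern in violet.  A capture event with no image
    is an error naming the event.
    """
    from .geometry import FrameSpec

    frames: list[np.ndarray] = []
    current_edge: Polyline | None = None
    current_pattern: np.ndarray | None = None
    captures = [e for e in log.events if e.kind == "capture"]
    if not captures:
        raise LoopError("log contains no capture events")
    by_time = log.events
    for e in by_time:
        if e.kind == "project":
            if e.edge is not None:
                current_edge = e.edge
            if e.pattern is not None:
                current_pattern = e.pattern
            continue
        if e.image is None:
            raise LoopError(
                f"missing image for capture event {e.index} at t={e.time_min:g} min"
            )
        h, w = e.image.shape
        rgb = np.stack([e.image] * 3, axis=-1).astype(np.uint8)
        if current_edge is not None and len(current_edge) >= 2:
            mask = rasterize_polyline(current_edge, FrameSpec(w, h), thickness=2)
            rgb[mask] = EDGE_COLOR
        if current_pattern is not None and calib is not None:
            ys, xs = np.nonzero(current_pattern)
            if len(xs):
                pts = calib.inverse().apply(
                    np.column_stack([xs, ys]).astype(float)
                )
                ix = np.rint(pts[:, 0]).astype(int)
                iy = np.rint(pts[:, 1]).astype(int)
                keep = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
                rgb[iy[keep], ix[keep]] = PATTERN_COLOR
        frames.append(rgb)
    stack = np.stack(frames)
    if outdir is not None:
        import pathlib

        import imageio.v3 as iio

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for k, fr in enumerate(stack):
            iio.imwrite(out / f"overlay_{k:04d}.png", fr)
    if stack_path is not None:
        import tifffile

        tifffile.imwrite(stack_path, stack)
    return stack
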