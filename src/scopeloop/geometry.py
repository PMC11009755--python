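"""Coordinate frames, affine maps and rasterisation primitives.

Conventions used across the package:

* pixel coordinates are 0-based, ``x`` runs rightward (column index) and
  ``y`` downward (row index);
* a pixel's centre sits at integer coordinates, so pixel ``(0, 0)`` covers
  the square ``[-0.5, 0.5) x [-0.5, 0.5)``;
* all public APIs take and return ``(x, y)`` pairs; image arrays are
  indexed ``[y, x]`` (row, column) as usual for numpy;
* sub-pixel positions are carried as floats everywhere and rounding only
  happens at rasterisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import approximate_polygon

__all__ = [
    "FrameSpec",
    "AffineMap",
    "Polyline",
    "DegenerateTransformError",
    "apply_map",
    "invert_map",
    "compose",
    "rasterize_polyline",
    "CAMERA_FRAME",
    "PROJECTOR_FRAME",
]

_DET_EPS = 1e-12


class DegenerateTransformError(ValueError):
    """The linear part of a transform is (numerically) singular."""


@dataclass(frozen=True)
class FrameSpec:
    """Pixel grid of one device ("camera" or "projector")."""

    width: int
    height: int
    name: str = "camera"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"frame must be at least 1x1, got {self.width}x{self.height}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Numpy array shape ``(height, width)``."""
        return (self.height, self.width)

    @property
    def size(self) -> tuple[int, int]:
        """``(width, height)`` pair."""
        return (self.width, self.height)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which ``(x, y)`` points fall on the pixel grid."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= -0.5)
            & (pts[:, 0] < self.width - 0.5)
            & (pts[:, 1] >= -0.5)
            & (pts[:, 1] < self.height - 0.5)
        )

    def corners(self) -> np.ndarray:
        """Outer corners of the pixel grid in continuous coordinates."""
        w, h = self.width, self.height
        return np.array(
            [
                [-0.5, -0.5],
                [w - 0.5, -0.5],
                [w - 0.5, h - 0.5],
                [-0.5, h - 0.5],
            ]
        )


#: Default camera frame: 1920 x 1088 sensor readout of the HQ camera at 10x.
CAMERA_FRAME = FrameSpec(1920, 1088, "camera")
#: Default projector frame; DLP pixel grids vary by model, so this is a
#: configurable default rather than something any algorithm relies on.
PROJECTOR_FRAME = FrameSpec(640, 360, "projector")


@dataclass(frozen=True, eq=False)
class AffineMap:
    """2x3 affine transform mapping ``(x, y)`` in ``source`` to ``target``.

    ``(x', y') = (a11 x + a12 y + a13,  a21 x + a22 y + a23)``
    """

    matrix: np.ndarray
    source: str = "camera"
    target: str = "projector"

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("affine matrix contains non-finite entries")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, source: str = "camera", target: str = "projector") -> "AffineMap":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), source, target)

    @classmethod
    def translation(cls, tx: float, ty: float, **kw) -> "AffineMap":
        return cls(np.array([[1.0, 0.0, tx], [0.0, 1.0, ty]]), **kw)

    @classmethod
    def scaling(cls, sx: float, sy: float | None = None, **kw) -> "AffineMap":
        sy = sx if sy is None else sy
        return cls(np.array([[sx, 0.0, 0.0], [0.0, sy, 0.0]]), **kw)

    @classmethod
    def from_linear(
        cls, linear: np.ndarray, translation: tuple[float, float] = (0.0, 0.0), **kw
    ) -> "AffineMap":
        lin = np.asarray(linear, dtype=float).reshape(2, 2)
        t = np.asarray(translation, dtype=float).reshape(2, 1)
        return cls(np.hstack([lin, t]), **kw)

    @classmethod
    def similarity(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
        **kw,
    ) -> "AffineMap":
        """Rotation-scale about ``center`` followed by ``translation``."""
        th = math.radians(rotation_deg)
        lin = scale * np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )
        c = np.asarray(center, dtype=float)
        t = c + np.asarray(translation, dtype=float) - lin @ c
        return cls.from_linear(lin, tuple(t), **kw)

    # -- core algebra ------------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.linear))

    @property
    def mean_scale(self) -> float:
        """Isotropic scale equivalent: sqrt(|det|) (area scale factor ** 0.5)."""
        return math.sqrt(abs(self.det))

    def apply(self, points):
        """Map points (or a :class:`Polyline`) from source to target frame."""
        if isinstance(points, Polyline):
            return Polyline(self.apply(points.vertices), frame=self.target)
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, 2)
        out = flat @ self.linear.T + self.offset
        return out.reshape(pts.shape)

    __call__ = apply

    def inverse(self) -> "AffineMap":
        if abs(self.det) < _DET_EPS:
            raise DegenerateTransformError(
                f"degenerate transform: |det| = {abs(self.det):.3g} < {_DET_EPS:g}"
            )
        inv = np.linalg.inv(self.linear)
        t = -inv @ self.offset
        return AffineMap(np.hstack([inv, t.reshape(2, 1)]), self.target, self.source)

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Map applying ``other`` first, then ``self``."""
        lin = self.linear @ other.linear
        t = self.linear @ other.offset + self.offset
        return AffineMap(np.hstack([lin, t.reshape(2, 1)]), other.source, self.target)

    def isclose(self, other: "AffineMap", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    def as_homogeneous(self) -> np.ndarray:
        """3x3 homogeneous matrix (useful for scikit-image transforms)."""
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "source": self.source,
            "target": self.target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineMap":
        return cls(np.array(d["matrix"], dtype=float), d.get("source", "camera"),
                   d.get("target", "projector"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "AffineMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:  # compact, for logs
        a = self.matrix
        return (
            f"AffineMap({self.source}->{self.target}, "
            f"[[{a[0,0]:.4g},{a[0,1]:.4g},{a[0,2]:.4g}],"
            f"[{a[1,0]:.4g},{a[1,1]:.4g},{a[1,2]:.4g}]])"
        )


@dataclass(frozen=True, eq=False)
class Polyline:
    """Ordered list of ``(x, y)`` vertices in a named frame."""

    vertices: np.ndarray
    frame: str = "camera"

    def __post_init__(self) -> None:
        v = np.array(self.vertices, dtype=float).reshape(-1, 2)
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("polyline contains non-finite vertices")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def length(self) -> float:
        """Polygonal arc length in pixels."""
        if len(self.vertices) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))

    @property
    def centroid(self) -> np.ndarray:
        if not len(self.vertices):
            raise ValueError("empty polyline has no centroid")
        return self.vertices.mean(axis=0)

    def simplify(self, tolerance: float = 0.5) -> "Polyline":
        """Douglas-Peucker simplification (keeps endpoints)."""
        if len(self.vertices) < 3 or tolerance <= 0:
            return self
        return Polyline(approximate_polygon(np.asarray(self.vertices), tolerance),
                        frame=self.frame)

    def resample(self, step: float = 1.0) -> np.ndarray:
        """Points along the line spaced ~``step`` px (for distance queries)."""
        v = self.vertices
        if len(v) < 2:
            return np.array(v, dtype=float)
        out = [v[0]]
        for p, q in zip(v[:-1], v[1:]):
            d = float(np.linalg.norm(q - p))
            n = max(1, int(math.ceil(d / step)))
            ts = np.linspace(0.0, 1.0, n + 1)[1:]
            out.extend(p + ts[:, None] * (q - p))
        return np.asarray(out)


def apply_map(m: AffineMap, points):
    """Functional alias for :meth:`AffineMap.apply`."""
    return m.apply(points)


def invert_map(m: AffineMap) -> AffineMap:
    """Functional alias for :meth:`AffineMap.inverse`."""
    return m.inverse()


def compose(outer: AffineMap, inner: AffineMap) -> AffineMap:
    """Map equivalent to applying ``inner`` first, then ``outer``."""
    return outer.compose(inner)


def rasterize_polyline(line, frame: FrameSpec, thickness: float = 1) -> np.ndarray:
    """Draw a polyline into a boolean frame-sized image.

    A pixel is on iff the Euclidean distance from its centre to the polyline
    is at most ``thickness / 2``.  Segments are clipped to the frame; an
    empty polyline gives an all-off image.
    """
    if thickness < 1:
        raise ValueError(f"thickness must be >= 1, got {thickness}")
    verts = line.vertices if isinstance(line, Polyline) else \
        np.asarray(line, dtype=float).reshape(-1, 2)
    out = np.zeros(frame.shape, dtype=bool)
    if len(verts) == 0:
        return out
    r = thickness / 2.0
    segments = (
        [(verts[0], verts[0])]
        if len(verts) == 1
        else list(zip(verts[:-1], verts[1:]))
    )
    h, w = frame.shape
    for p, q in segments:
        x0 = max(0, int(math.floor(min(p[0], q[0]) - r)))
        x1 = min(w - 1, int(math.ceil(max(p[0], q[0]) + r)))
        y0 = max(0, int(math.floor(min(p[1], q[1]) - r)))
        y1 = min(h - 1, int(math.ceil(max(p[1], q[1]) + r)))
        if x0 > x1 or y0 > y1:
            continue
        xs = np.arange(x0, x1 + 1, dtype=float)
        ys = np.arange(y0, y1 + 1, dtype=float)
        X, Y = np.meshgrid(xs, ys)
        d = q - p
        l2 = float(d @ d)
        if l2 == 0.0:
            dist = np.hypot(X - p[0], Y - p[1])
        else:
            t = np.clip(((X - p[0]) * d[0] + (Y - p[1]) * d[1]) / l2, 0.0, 1.0)
            dist = np.hypot(X - (p[0] + t * d[0]), Y - (p[1] + t * d[1]))
        out[y0 : y1 + 1, x0 : x1 + 1] |= dist <= r + 1e-9
    return out
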