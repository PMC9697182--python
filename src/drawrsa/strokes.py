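"""Vector strokes: the primitive the stimulus templates and simulated drawings are built from.

A stroke is a named polyline in canvas coordinates (pixels, origin top-left);
a stroke set is an ordered tuple of strokes.  All geometry helpers are pure
and operate on float64 ``(n, 2)`` arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Stroke", "StrokeSet", "circle_points", "arc_points"]


@dataclass(frozen=True)
class Stroke:
    """A named open or closed polyline."""

    name: str
    points: np.ndarray  # (n, 2) float64, n >= 2

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError(f"stroke {self.name!r} needs an (n>=2, 2) point array")
        object.__setattr__(self, "points", pts)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def translated(self, offset) -> "Stroke":
        return Stroke(self.name, self.points + np.asarray(offset, dtype=np.float64))

    def jittered(self, rng: np.random.Generator, sd: float) -> "Stroke":
        """Per-point Gaussian jitter plus a whole-stroke offset of the same scale."""
        offset = rng.normal(0.0, sd, size=2)
        noise = rng.normal(0.0, sd, size=self.points.shape)
        return Stroke(self.name, self.points + noise + offset)


@dataclass(frozen=True)
class StrokeSet:
    strokes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strokes", tuple(self.strokes))

    def __len__(self) -> int:
        return len(self.strokes)

    def __iter__(self):
        return iter(self.strokes)

    def __bool__(self) -> bool:
        return len(self.strokes) > 0

    @property
    def names(self) -> tuple:
        return tuple(s.name for s in self.strokes)

    def bounding_box(self) -> tuple:
        """(xmin, ymin, xmax, ymax) over all points; raises on an empty set."""
        if not self.strokes:
            raise ValueError("bounding box of an empty stroke set")
        pts = np.vstack([s.points for s in self.strokes])
        xmin, ymin = pts.min(axis=0)
        xmax, ymax = pts.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)

    def translated(self, offset) -> "StrokeSet":
        return StrokeSet(tuple(s.translated(offset) for s in self.strokes))

    def jittered(self, rng: np.random.Generator, sd: float) -> "StrokeSet":
        return StrokeSet(tuple(s.jittered(rng, sd) for s in self.strokes))

    def equals(self, other: "StrokeSet", tol: float = 0.0) -> bool:
        if self.names != other.names:
            return False
        for a, b in zip(self.strokes, other.strokes):
            if a.points.shape != b.points.shape:
                return False
            if not np.allclose(a.points, b.points, atol=tol, rtol=0.0):
                return False
        return True


def circle_points(cx: float, cy: float, r: float, n: int = 32) -> np.ndarray:
    """Closed n-gon approximation of a circle (first point repeated at the end)."""
    t = np.linspace(0.0, 2.0 * np.pi, n + 1)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def arc_points(cx: float, cy: float, r: float, deg0: float, deg1: float, n: int = 16) -> np.ndarray:
    t = np.radians(np.linspace(deg0, deg1, n))
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
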