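"""Shared domain types for the vocal-tract modulation pipeline.

Coordinate convention: origin at the top-left pixel centre of the image,
x increasing rightward, y increasing downward, units millimetres.  All
outlines are reported in the registered reference space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Polygon


class GeometryError(ValueError):
    """Raised when generated or transformed geometry leaves the field of view."""


class EstimationError(RuntimeError):
    """Raised when an estimator has no information to work with (e.g. flat mask)."""


class ExtractionError(RuntimeError):
    """Raised when no air-region boundary can be extracted from a tissue mask."""


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid-body transform: rotation about a pivot, then translation.

    ``rotation_deg`` is counter-clockwise in the (x right, y down) frame;
    ``translation_mm`` is an (x, y) shift in mm.  The pivot is supplied when
    the transform is applied (by default the image centre).
    """

    rotation_deg: float = 0.0
    translation_mm: tuple[float, float] = (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])

    def apply_points(self, points: np.ndarray, pivot: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points in mm."""
        pts = np.asarray(points, dtype=float)
        pivot = np.asarray(pivot, dtype=float)
        return (pts - pivot) @ self.matrix().T + pivot + np.asarray(self.translation_mm)

    def inverse(self) -> "RigidTransform":
        R = self.matrix()
        t = np.asarray(self.translation_mm)
        ti = -R.T @ t
        return RigidTransform(-self.rotation_deg, (float(ti[0]), float(ti[1])))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        R = self.matrix()
        t = R @ np.asarray(other.translation_mm) + np.asarray(self.translation_mm)
        return RigidTransform(self.rotation_deg + other.rotation_deg, (float(t[0]), float(t[1])))


@dataclass
class ImageFrame:
    """One 2D midsagittal intensity frame with its condition labels."""

    intensities: np.ndarray
    pixel_size_mm: float
    frame_index: int = 0
    speaker_id: str = ""
    word: str = ""
    vt_condition: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("frame intensities must be a 2D array")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def centre_mm(self) -> tuple[float, float]:
        nr, nc = self.intensities.shape
        return ((nc - 1) / 2 * self.pixel_size_mm, (nr - 1) / 2 * self.pixel_size_mm)


@dataclass
class ImageSeries:
    """A stack of frames sharing one geometry, with per-frame labels."""

    frames: list[ImageFrame]

    def __post_init__(self) -> None:
        if self.frames:
            shape = self.frames[0].shape
            if any(f.shape != shape for f in self.frames):
                raise ValueError("all frames in a series must share one shape")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]

    @property
    def pixel_size_mm(self) -> float:
        return self.frames[0].pixel_size_mm

    def as_array(self) -> np.ndarray:
        return np.stack([f.intensities for f in self.frames])


@dataclass
class PixelMask:
    """Boolean pixel mask aligned with the reference frame geometry."""

    mask: np.ndarray
    kind: str = "static_structures"  # static_structures | labile_candidates | tissue
    low_contrast: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class VTOutline:
    """Ordered trace of the vocal-tract air-tissue boundary, in mm.

    Closed outlines do not repeat the first point at the end.
    """

    points: np.ndarray
    closed: bool = True
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("outline points must be an (N, 2) array")
        if self.closed and len(self.points) > 1 and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]

    def __len__(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))

    def is_simple(self) -> bool:
        if self.closed:
            return Polygon(self.points).is_valid
        return LineString(self.points).is_simple

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise order in (x, y-down)."""
        x, y = self.points.T
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the points ordered counter-clockwise (positive shoelace area)."""
    x, y = np.asarray(points, float).T
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return np.asarray(points, float)[::-1].copy() if area < 0 else np.asarray(points, float)


def polyline_length(points: np.ndarray, closed: bool = False) -> float:
    pts = np.asarray(points, float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
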