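"""Domain types and polygon geometry for whole-plant corn silage (WPCS) samples.

Images of chopped silage are annotated with polygon instances of kernel
fragments or stover overlength particles.  Everything downstream (dataset
statistics, inter-annotator agreement, sieve-score estimation, detection
evaluation) works on these types.

Coordinates are pixel coordinates, origin top-left, 0-based.  Polygons are
stored as open vertex rings (the closing vertex is not repeated) oriented
counter-clockwise.  Physical sizes come from a pixels-per-millimetre
calibration; the capture rig used throughout resolves 20 px per mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry.polygon import orient

__all__ = [
    "LABELS",
    "Calibration",
    "HarvestMeta",
    "ImageRecord",
    "Instance",
    "AnnotationSet",
    "ShapeSummary",
    "canonicalize_polygon",
    "polygon_area",
    "polygon_iou",
    "shape_summary",
]

#: The five-class taxonomy: kernel material plus the four stover classes.
LABELS = (
    "kernel_fragment",
    "accepted_leaf",
    "non_accepted_leaf",
    "inner_stalk",
    "outer_stalk",
)

STOVER_LABELS = LABELS[1:]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical calibration.

    Parameters
    ----------
    px_per_mm
        Image resolution in pixels per millimetre.  The default of 20 matches
        the sample-capture hardware the datasets were recorded with.
    """

    px_per_mm: float = 20.0

    def __post_init__(self) -> None:
        if not self.px_per_mm > 0:
            raise ValueError(f"px_per_mm must be positive, got {self.px_per_mm}")

    def px_to_mm(self, px: float) -> float:
        return px / self.px_per_mm

    def px2_to_mm2(self, px2: float) -> float:
        return px2 / self.px_per_mm**2


@dataclass(frozen=True)
class HarvestMeta:
    """Machine settings and provenance of one harvested image sequence.

    ``pg_mm`` is the Processor Gap (distance between the kernel-cracking
    rolls); ``tloc_mm`` the Theoretical Length of Cut (nominal chop length).
    Smaller PG cracks kernels into more, smaller fragments; TLOC governs
    stover particle length and hence the overlength definition.
    """

    year: int
    sequence_id: str
    pg_mm: float
    tloc_mm: float
    calendar_week: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.pg_mm > 0:
            raise ValueError(f"pg_mm must be positive, got {self.pg_mm}")
        if not self.tloc_mm > 0:
            raise ValueError(f"tloc_mm must be positive, got {self.tloc_mm}")


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    width_px: int
    height_px: int
    calibration: Calibration
    meta: HarvestMeta

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError(
                f"image {self.image_id!r}: non-positive size "
                f"{self.width_px}x{self.height_px}"
            )


def canonicalize_polygon(vertices: Sequence[Sequence[float]]) -> np.ndarray:
    """Validate and canonicalize a polygon vertex list.

    Drops a repeated closing vertex and consecutive duplicates, enforces
    counter-clockwise orientation, and rejects degenerate or self-intersecting
    rings.  Returns an (n, 2) float array, n >= 3.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"polygon must be an (n, 2) vertex list, got shape {pts.shape}")
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # drop consecutive duplicates
    if len(pts) >= 2:
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
        pts = pts[keep]
    if len(pts) < 3:
        raise ValueError(f"polygon has fewer than 3 distinct vertices: {len(pts)}")
    ring = ShapelyPolygon(pts)
    if not ring.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    if ring.area <= 0:
        raise ValueError("polygon has zero area")
    ring = orient(ring, sign=1.0)  # CCW
    out = np.asarray(ring.exterior.coords[:-1], dtype=float)
    return out


@dataclass(frozen=True)
class Instance:
    """One annotated or predicted particle.

    ``score`` is present iff the instance is a detector prediction; manual
    annotations carry no score.
    """

    instance_id: str
    image_id: str
    label: str
    polygon: np.ndarray
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"instance {self.instance_id!r}: unknown label {self.label!r}; "
                f"expected one of {LABELS}"
            )
        object.__setattr__(self, "polygon", canonicalize_polygon(self.polygon))
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"instance {self.instance_id!r}: score {self.score} outside [0, 1]"
            )

    def to_shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)

    def with_polygon(self, vertices: Sequence[Sequence[float]]) -> "Instance":
        return replace(self, polygon=np.asarray(vertices, dtype=float))


@dataclass
class AnnotationSet:
    """Instances from one source: an annotator, ground truth, or a detector."""

    source_id: str
    images: dict[str, ImageRecord] = field(default_factory=dict)
    instances: list[Instance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for inst in self.instances:
            if inst.image_id not in self.images:
                raise ValueError(
                    f"instance {inst.instance_id!r} references missing image "
                    f"{inst.image_id!r}"
                )
            if inst.instance_id in seen:
                raise ValueError(f"duplicate instance id {inst.instance_id!r}")
            seen.add(inst.instance_id)

    def instances_in(self, image_id: str) -> list[Instance]:
        return [i for i in self.instances if i.image_id == image_id]

    def filter_instances(self, keep) -> "AnnotationSet":
        return AnnotationSet(
            source_id=self.source_id,
            images=dict(self.images),
            instances=[i for i in self.instances if keep(i)],
        )

    def __len__(self) -> int:
        return len(self.instances)


@dataclass(frozen=True)
class ShapeSummary:
    area_px2: float
    area_mm2: float
    major_axis_mm: float
    minor_axis_mm: float


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a canonical (CCW, open) polygon, in px^2."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _min_rect_axes_px(poly: ShapelyPolygon) -> tuple[float, float]:
    """Side lengths (major, minor) of the minimum-area enclosing rotated
    rectangle, in px."""
    rect = poly.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)
    if len(coords) < 4:  # degenerate: a segment or point
        raise ValueError("degenerate polygon: minimum rectangle collapsed")
    e1 = float(np.hypot(*(coords[1] - coords[0])))
    e2 = float(np.hypot(*(coords[2] - coords[1])))
    return max(e1, e2), min(e1, e2)


def _moment_ellipse_axes_px(poly: ShapelyPolygon) -> tuple[float, float]:
    """Axis lengths of the area-equivalent second-moment ellipse, in px.

    For a uniform ellipse with semi-axes (a, b) the central second moments are
    (a^2/4, b^2/4); invert that relation on the polygon's moments.
    """
    verts = np.asarray(orient(poly, sign=1.0).exterior.coords)
    x, y = verts[:-1, 0], verts[:-1, 1]
    xn, yn = verts[1:, 0], verts[1:, 1]
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    x, xn = x - cx, xn - cx
    y, yn = y - cy, yn - cy
    cross = x * yn - xn * y
    ixx = (cross * (y * y + y * yn + yn * yn)).sum() / 12.0
    iyy = (cross * (x * x + x * xn + xn * xn)).sum() / 12.0
    ixy = (cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)).sum() / 24.0
    cov = np.array([[iyy, ixy], [ixy, ixx]]) / area  # normalised second moments
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    minor, major = 4.0 * np.sqrt(eig)  # full axis lengths
    return float(major), float(minor)


def shape_summary(
    inst: Instance,
    cal: Calibration,
    axis_mode: Literal["min_rect", "moment_ellipse"] = "min_rect",
) -> ShapeSummary:
    """Area and major/minor axis lengths of one instance.

    The default axis definition is the side lengths of the minimum-area
    enclosing rotated rectangle — the physical reading used by the sieve and
    overlength rules (the longest extent of the particle, and its smallest
    cross-section).  ``moment_ellipse`` selects the second-moment equivalent
    ellipse instead, for sensitivity checks.
    """
    poly = inst.to_shapely()
    area_px2 = polygon_area(inst.polygon)
    if area_px2 <= 0:
        raise ValueError(f"instance {inst.instance_id!r}: degenerate polygon")
    if axis_mode == "min_rect":
        major_px, minor_px = _min_rect_axes_px(poly)
    elif axis_mode == "moment_ellipse":
        major_px, minor_px = _moment_ellipse_axes_px(poly)
    else:
        raise ValueError(f"unknown axis_mode {axis_mode!r}")
    return ShapeSummary(
        area_px2=area_px2,
        area_mm2=cal.px2_to_mm2(area_px2),
        major_axis_mm=cal.px_to_mm(major_px),
        minor_axis_mm=cal.px_to_mm(minor_px),
    )


def polygon_iou(a: Sequence[Sequence[float]], b: Sequence[Sequence[float]]) -> float:
    """Exact polygon Intersection-over-Union.

    Symmetric, in [0, 1]; 1 iff the two regions are geometrically identical.
    """
    pa = ShapelyPolygon(np.asarray(a, dtype=float))
    pb = ShapelyPolygon(np.asarray(b, dtype=float))
    for name, p in (("a", pa), ("b", pb)):
        if not p.is_valid or p.area <= 0:
            raise ValueError(f"polygon {name} is invalid or degenerate")
    # geometric overlay is not bitwise-commutative; fix the operand order so
    # iou(a, b) == iou(b, a) exactly
    if pa.wkb > pb.wkb:
        pa, pb = pb, pa
    inter = pa.intersection(pb).area
    if inter == 0.0:
        return 0.0
    union = pa.area + pb.area - inter
    return float(inter / union)


def bbox_iou(a: Sequence[Sequence[float]], b: Sequence[Sequence[float]]) -> float:
    """Axis-aligned bounding-box IoU of two polygons (box-detector mode)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ax0, ay0 = a.min(axis=0)
    ax1, ay1 = a.max(axis=0)
    bx0, by0 = b.min(axis=0)
    bx1, by1 = b.max(axis=0)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union)
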