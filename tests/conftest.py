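"""Shared fixtures: small hand-built annotation sets and polygon helpers."""

from __future__ import annotations

import numpy as np
import pytest

from silageqc.core import (
    AnnotationSet,
    Calibration,
    HarvestMeta,
    ImageRecord,
    Instance,
)


def square(x: float, y: float, side: float) -> list[list[float]]:
    """Axis-aligned square with top-left corner (x, y)."""
    return [[x, y], [x + side, y], [x + side, y + side], [x, y + side]]


def make_image(
    image_id: str = "img0",
    size: int = 1000,
    pg_mm: float = 2.0,
    tloc_mm: float = 4.0,
    week: str | None = None,
    px_per_mm: float = 20.0,
) -> ImageRecord:
    return ImageRecord(
        image_id=image_id,
        width_px=size,
        height_px=size,
        calibration=Calibration(px_per_mm=px_per_mm),
        meta=HarvestMeta(
            year=2018, sequence_id="seq0", pg_mm=pg_mm, tloc_mm=tloc_mm,
            calendar_week=week,
        ),
    )


def make_set(
    polygons: list[list[list[float]]],
    source_id: str = "gt",
    label: str = "kernel_fragment",
    scores: list[float] | None = None,
    image: ImageRecord | None = None,
) -> AnnotationSet:
    """One-image annotation set from a list of polygons."""
    rec = image or make_image()
    return AnnotationSet(
        source_id=source_id,
        images={rec.image_id: rec},
        instances=[
            Instance(
                instance_id=f"{source_id}-{k:03d}",
                image_id=rec.image_id,
                label=label,
                polygon=poly,
                score=None if scores is None else scores[k],
            )
            for k, poly in enumerate(polygons)
        ],
    )


@pytest.fixture
def cal() -> Calibration:
    return Calibration()


@pytest.fixture
def two_square_set() -> AnnotationSet:
    return make_set([square(10, 10, 40), square(200, 200, 80)])


def random_convex_polygon(
    rng: np.random.Generator, center: np.ndarray, scale: float, n: int = 12
) -> np.ndarray:
    """Random convex polygon: convex hull of noisy ellipse samples."""
    from shapely.geometry import Polygon as SP

    theta = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    a = scale * rng.uniform(0.5, 1.0)
    b = scale * rng.uniform(0.2, 0.5)
    r = 1.0 + 0.15 * rng.standard_normal(n)
    pts = np.column_stack(
        [a * np.clip(r, 0.3, None) * np.cos(theta), b * np.clip(r, 0.3, None) * np.sin(theta)]
    )
    rot = rng.uniform(0, np.pi)
    mat = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    hull = SP(pts @ mat.T + center).convex_hull
    return np.asarray(hull.exterior.coords[:-1], dtype=float)
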