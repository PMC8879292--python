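"""Synthetic WPCS annotation sets with the statistical structure the analyses
assume.

No image dataset of whole-plant corn silage is publicly deposited, so every
downstream stage is exercised on simulated data.  The generator reproduces
the machine-setting effects the analyses probe: a smaller Processor Gap (PG)
yields more and smaller kernel fragments; a shorter Theoretical Length of Cut
(TLOC) yields more overlength stover.  Corruption profiles emulate annotator
inconsistency (misses, boundary jitter, spurious and merged instances),
detector profiles emulate imperfect predictors, and a sieving simulator
produces physically sieved CSPS values correlated with image content.

Default effect sizes are set to reproduce the qualitative 2018-season pattern
(about 28 instances per image at PG 1 mm falling to about 10 at PG 4 mm for
the longer chop length) without claiming exact counts.

All generators are pure functions of (inputs, seed).  Randomness is split
into per-image substreams keyed by image index, so per-image results do not
depend on image order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon

from .core import (
    AnnotationSet,
    polygon_area,
    Calibration,
    HarvestMeta,
    ImageRecord,
    Instance,
    STOVER_LABELS,
    shape_summary,
)

__all__ = [
    "CountModel",
    "SizeModel",
    "StoverModel",
    "HarvestSimConfig",
    "AnnotatorProfile",
    "DetectorProfile",
    "SievingRecord",
    "generate_harvest",
    "corrupt_annotations",
    "simulate_detector",
    "simulate_sieving",
]


def _image_rng(seed: int, image_index: int, salt: int = 0) -> np.random.Generator:
    """Counter-based per-image substream: independent of image order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(salt, image_index))
    )


@dataclass(frozen=True)
class CountModel:
    """Kernel-fragment count per image: negative binomial with mean
    ``base_rate * exp(pg_slope * pg_mm)``.

    Overdispersed counts match the within-setting spread seen across real
    sequences; ``dispersion`` is the NB shape (larger = closer to Poisson).
    """

    base_rate: float = 38.8
    pg_slope: float = -0.327  # per mm of PG; negative: wider gap, fewer fragments
    dispersion: float = 8.0

    def mean(self, pg_mm: float) -> float:
        return self.base_rate * math.exp(self.pg_slope * pg_mm)


@dataclass(frozen=True)
class SizeModel:
    """Lognormal kernel-fragment major axis (mm), location increasing in PG."""

    log_mean_mm: float = 0.93  # log major axis at PG -> 0
    pg_slope: float = 0.17  # per mm of PG
    log_sd: float = 0.35
    aspect_range: tuple[float, float] = (0.4, 0.8)  # minor/major

    def log_location(self, pg_mm: float) -> float:
        return self.log_mean_mm + self.pg_slope * pg_mm


@dataclass(frozen=True)
class StoverModel:
    """Overlength stover occurrence: Poisson rate decreasing in TLOC, sizes
    lognormal above the 1.5 x TLOC threshold, classes from ``class_mix``."""

    base_rate: float = 12.0  # overlengths per image at TLOC -> 0
    tloc_slope: float = -0.18  # per mm of TLOC
    # accepted_leaf, non_accepted_leaf, inner_stalk, outer_stalk
    class_mix: tuple[float, float, float, float] = (0.42, 0.34, 0.06, 0.18)
    log_excess_mean: float = 0.25  # log of major-axis / threshold ratio
    log_excess_sd: float = 0.20
    aspect_range: tuple[float, float] = (0.15, 0.45)

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {sum(self.class_mix)}")

    def rate(self, tloc_mm: float) -> float:
        return self.base_rate * math.exp(self.tloc_slope * tloc_mm)


@dataclass(frozen=True)
class HarvestSimConfig:
    n_images: int = 50
    pg_mm: float = 2.0
    tloc_mm: float = 6.0
    image_size_px: tuple[int, int] = (1024, 1024)
    px_per_mm: float = 20.0
    count_model: CountModel = field(default_factory=CountModel)
    size_model: SizeModel = field(default_factory=SizeModel)
    stover_model: Optional[StoverModel] = None
    year: int = 2018
    sequence_id: str = "sim"
    calendar_week: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px[0] <= 0 or self.image_size_px[1] <= 0:
            raise ValueError(f"non-positive image size {self.image_size_px}")
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")


def _blob_polygon(
    rng: np.random.Generator,
    center: np.ndarray,
    major_px: float,
    minor_px: float,
    angle: float,
    n_vertices: Optional[int] = None,
    roughness: float = 0.08,
) -> np.ndarray:
    """Irregular convex particle outline: a noisy ellipse discretization whose
    convex hull guarantees a simple polygon with controllable axes."""
    n = int(n_vertices if n_vertices is not None else rng.integers(12, 25))
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    radial = 1.0 + roughness * rng.standard_normal(n)
    radial = np.clip(radial, 0.3, None)
    x = 0.5 * major_px * radial * np.cos(theta)
    y = 0.5 * minor_px * radial * np.sin(theta)
    c, s = math.cos(angle), math.sin(angle)
    pts = np.column_stack([c * x - s * y, s * x + c * y]) + center
    hull = ShapelyPolygon(pts).convex_hull
    return np.asarray(hull.exterior.coords[:-1], dtype=float)


def _place_center(
    rng: np.random.Generator, size_px: tuple[int, int], extent_px: float
) -> np.ndarray:
    margin = min(0.5 * extent_px + 2.0, 0.45 * min(size_px))
    return np.array(
        [
            rng.uniform(margin, size_px[0] - margin),
            rng.uniform(margin, size_px[1] - margin),
        ]
    )


def generate_harvest(cfg: HarvestSimConfig) -> AnnotationSet:
    """Simulate one harvested, imaged and perfectly annotated sequence.

    Per image the kernel-fragment count is negative-binomial with mean
    ``base_rate * exp(pg_slope * pg_mm)`` and each fragment's major axis is
    lognormal with location increasing in PG.  If a stover model is present,
    overlength particles are added at a Poisson rate decreasing in TLOC.
    Deterministic given ``cfg.seed``.
    """
    cal = Calibration(px_per_mm=cfg.px_per_mm)
    meta = HarvestMeta(
        year=cfg.year,
        sequence_id=cfg.sequence_id,
        pg_mm=cfg.pg_mm,
        tloc_mm=cfg.tloc_mm,
        calendar_week=cfg.calendar_week,
    )
    images: dict[str, ImageRecord] = {}
    instances: list[Instance] = []
    cm, sm = cfg.count_model, cfg.size_model
    mu = cm.mean(cfg.pg_mm)

    for i in range(cfg.n_images):
        rng = _image_rng(cfg.seed, i)
        image_id = f"{cfg.sequence_id}-img{i:04d}"
        images[image_id] = ImageRecord(
            image_id=image_id,
            width_px=cfg.image_size_px[0],
            height_px=cfg.image_size_px[1],
            calibration=cal,
            meta=meta,
        )
        if mu > 0:
            p = cm.dispersion / (cm.dispersion + mu)
            count = int(rng.negative_binomial(cm.dispersion, p))
        else:
            count = 0
        for k in range(count):
            major_mm = float(
                np.exp(sm.log_location(cfg.pg_mm) + sm.log_sd * rng.standard_normal())
            )
            aspect = rng.uniform(*sm.aspect_range)
            major_px = major_mm * cfg.px_per_mm
            center = _place_center(rng, cfg.image_size_px, major_px)
            poly = _blob_polygon(
                rng, center, major_px, aspect * major_px, rng.uniform(0, math.pi)
            )
            instances.append(
                Instance(
                    instance_id=f"{image_id}-kf{k:04d}",
                    image_id=image_id,
                    label="kernel_fragment",
                    polygon=poly,
                )
            )
        if cfg.stover_model is not None:
            st = cfg.stover_model
            n_stover = int(rng.poisson(st.rate(cfg.tloc_mm)))
            threshold_mm = 1.5 * cfg.tloc_mm
            for k in range(n_stover):
                major_mm = threshold_mm * float(
                    np.exp(st.log_excess_mean + st.log_excess_sd * rng.standard_normal())
                )
                aspect = rng.uniform(*st.aspect_range)
                major_px = min(major_mm * cfg.px_per_mm, 0.9 * min(cfg.image_size_px))
                center = _place_center(rng, cfg.image_size_px, major_px)
                label = STOVER_LABELS[int(rng.choice(4, p=st.class_mix))]
                poly = _blob_polygon(
                    rng, center, major_px, aspect * major_px, rng.uniform(0, math.pi)
                )
                instances.append(
                    Instance(
                        instance_id=f"{image_id}-st{k:04d}",
                        image_id=image_id,
                        label=label,
                        polygon=poly,
                    )
                )

    return AnnotationSet(source_id="gt", images=images, instances=instances)


@dataclass(frozen=True)
class AnnotatorProfile:
    """Stochastic model of one annotator's inconsistency.

    ``miss_base`` is the miss probability for a reference-size particle and
    ``miss_size_slope`` (per mm of major axis, usually negative) makes smaller
    particles more likely to be missed.  Surviving outlines receive Gaussian
    vertex jitter; spurious instances appear at ``false_positive_rate`` per
    image; with ``merge_prob`` closely grouped pairs are traced as one blob —
    the grouped-fragment ambiguity real annotators face.
    """

    miss_base: float = 0.2
    miss_size_slope: float = -0.02
    vertex_jitter_px: float = 2.0
    false_positive_rate: float = 0.5
    merge_prob: float = 0.0
    merge_gap_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_base <= 1.0:
            raise ValueError("miss_base must lie in [0, 1]")
        if not 0.0 <= self.merge_prob <= 1.0:
            raise ValueError("merge_prob must lie in [0, 1]")
        if self.vertex_jitter_px < 0 or self.false_positive_rate < 0:
            raise ValueError("jitter and false-positive rate must be >= 0")

    def miss_prob(self, major_mm: float) -> float:
        return float(np.clip(self.miss_base + self.miss_size_slope * major_mm, 0, 1))


def _jitter_polygon(
    rng: np.random.Generator, poly: np.ndarray, sd_px: float
) -> np.ndarray:
    if sd_px == 0:
        return poly
    out = poly + rng.normal(0.0, sd_px, size=poly.shape)
    p = ShapelyPolygon(out)
    if not p.is_valid or p.area <= 0:  # jitter can self-intersect; fall back to hull
        p = ShapelyPolygon(out).convex_hull
    return np.asarray(p.exterior.coords[:-1], dtype=float)


def corrupt_annotations(gt: AnnotationSet, prof: AnnotatorProfile) -> AnnotationSet:
    """Derive an inconsistent annotator's set from ground truth.

    Deterministic given ``prof.seed``; the zero profile is the identity and a
    total-miss profile empties the set.
    """
    out: list[Instance] = []
    image_ids = sorted(gt.images)
    for i, image_id in enumerate(image_ids):
        rng = _image_rng(prof.seed, i, salt=1)
        rec = gt.images[image_id]
        cal = rec.calibration
        kept: list[Instance] = []
        for inst in gt.instances_in(image_id):
            major_mm = shape_summary(inst, cal).major_axis_mm
            if rng.random() < prof.miss_prob(major_mm):
                continue
            kept.append(inst)

        # merge closely grouped pairs into one convex outline
        if prof.merge_prob > 0 and len(kept) >= 2:
            polys = [k.to_shapely() for k in kept]
            merged: list[Instance] = []
            used = [False] * len(kept)
            for a in range(len(kept)):
                if used[a]:
                    continue
                partner = -1
                for b in range(a + 1, len(kept)):
                    if used[b]:
                        continue
                    if (
                        kept[a].label == kept[b].label
                        and polys[a].distance(polys[b]) <= prof.merge_gap_px
                        and rng.random() < prof.merge_prob
                    ):
                        partner = b
                        break
                if partner >= 0:
                    used[a] = used[partner] = True
                    hull = polys[a].union(polys[partner]).convex_hull
                    merged.append(
                        Instance(
                            instance_id=f"{kept[a].instance_id}+m",
                            image_id=image_id,
                            label=kept[a].label,
                            polygon=np.asarray(hull.exterior.coords[:-1]),
                        )
                    )
                else:
                    used[a] = True
                    merged.append(kept[a])
            kept = merged

        for inst in kept:
            out.append(
                Instance(
                    instance_id=inst.instance_id,
                    image_id=image_id,
                    label=inst.label,
                    polygon=_jitter_polygon(rng, inst.polygon, prof.vertex_jitter_px),
                )
            )

        n_fp = int(rng.poisson(prof.false_positive_rate))
        labels = sorted({i.label for i in gt.instances}) or ["kernel_fragment"]
        for k in range(n_fp):
            major_px = rng.uniform(2.0, 6.0) * cal.px_per_mm
            center = _place_center(rng, (rec.width_px, rec.height_px), major_px)
            poly = _blob_polygon(
                rng,
                center,
                major_px,
                rng.uniform(0.4, 0.8) * major_px,
                rng.uniform(0, math.pi),
            )
            out.append(
                Instance(
                    instance_id=f"{image_id}-fp{k:03d}",
                    image_id=image_id,
                    label=labels[int(rng.integers(len(labels)))],
                    polygon=poly,
                )
            )

    return AnnotationSet(
        source_id=f"annotator-{prof.seed}", images=dict(gt.images), instances=out
    )


@dataclass(frozen=True)
class DetectorProfile:
    """Stochastic model of a trained detector's output quality.

    ``recall_curve`` maps particle major axis (mm) to detection probability
    (linear interpolation between knots, clamped at the ends).  True
    positives are jittered copies of the annotated outline with scores from
    ``Beta(score_tp)``; false positives are random blobs with scores from
    ``Beta(score_fp)`` at ``fp_rate`` per image.
    """

    recall_curve: tuple[tuple[float, float], ...] = ((1.0, 0.55), (4.0, 0.85), (10.0, 0.95))
    localization_jitter_px: float = 2.0
    score_tp: tuple[float, float] = (8.0, 2.0)
    score_fp: tuple[float, float] = (2.0, 5.0)
    fp_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b in (self.score_tp, self.score_fp):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        for _, p in self.recall_curve:
            if not 0.0 <= p <= 1.0:
                raise ValueError("recall probabilities must lie in [0, 1]")

    def recall_at(self, size_mm: float) -> float:
        xs = np.array([x for x, _ in self.recall_curve])
        ps = np.array([p for _, p in self.recall_curve])
        return float(np.interp(size_mm, xs, ps))


def _beta_or_const(rng: np.random.Generator, ab: tuple[float, float]) -> float:
    a, b = ab
    if math.isinf(a):  # degenerate "always 1.0" profile used for perfect detectors
        return 1.0
    return float(rng.beta(a, b))


def simulate_detector(gt: AnnotationSet, prof: DetectorProfile) -> AnnotationSet:
    """Simulate scored detections for every image of ``gt``."""
    out: list[Instance] = []
    image_ids = sorted(gt.images)
    for i, image_id in enumerate(image_ids):
        rng = _image_rng(prof.seed, i, salt=2)
        rec = gt.images[image_id]
        cal = rec.calibration
        k = 0
        for inst in gt.instances_in(image_id):
            major_mm = shape_summary(inst, cal).major_axis_mm
            if rng.random() >= prof.recall_at(major_mm):
                continue
            poly = _jitter_polygon(rng, inst.polygon, prof.localization_jitter_px)
            out.append(
                Instance(
                    instance_id=f"{image_id}-det{k:04d}",
                    image_id=image_id,
                    label=inst.label,
                    polygon=poly,
                    score=_beta_or_const(rng, prof.score_tp),
                )
            )
            k += 1
        labels = sorted({i.label for i in gt.instances}) or ["kernel_fragment"]
        for _ in range(int(rng.poisson(prof.fp_rate))):
            major_px = rng.uniform(2.0, 6.0) * cal.px_per_mm
            center = _place_center(rng, (rec.width_px, rec.height_px), major_px)
            poly = _blob_polygon(
                rng,
                center,
                major_px,
                rng.uniform(0.4, 0.8) * major_px,
                rng.uniform(0, math.pi),
            )
            out.append(
                Instance(
                    instance_id=f"{image_id}-det{k:04d}",
                    image_id=image_id,
                    label=labels[int(rng.integers(len(labels)))],
                    polygon=poly,
                    score=_beta_or_const(rng, prof.score_fp),
                )
            )
            k += 1
    return AnnotationSet(source_id="detector", images=dict(gt.images), instances=out)


@dataclass(frozen=True)
class SievingRecord:
    """One physically sieved sample: the laboratory CSPS percentage."""

    sample_id: str
    calendar_week: str
    csps_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.csps_percent <= 100.0:
            raise ValueError(f"csps_percent {self.csps_percent} outside [0, 100]")


def simulate_sieving(
    gt: AnnotationSet,
    cal: Calibration,
    noise_sd: float,
    seed: int = 0,
    aperture_mm: float = 4.75,
    group_by: Literal["image", "sequence"] = "image",
) -> list[SievingRecord]:
    """Simulate laboratory sieving of the samples behind an annotation set.

    The noise-free physical CSPS of a sample group is the area-weighted
    fraction of its kernel fragments whose minor axis (smallest cross-section,
    from the minimum enclosing rotated rectangle) is below the 4.75 mm sieve
    aperture.  Gaussian measurement noise of ``noise_sd`` CSPS points is
    added and the result clipped to [0, 100].
    """
    groups: dict[str, list[Instance]] = {}
    weeks: dict[str, str] = {}
    for inst in gt.instances:
        if inst.label != "kernel_fragment":
            continue
        rec = gt.images[inst.image_id]
        key = rec.image_id if group_by == "image" else rec.meta.sequence_id
        groups.setdefault(key, []).append(inst)
        weeks[key] = rec.meta.calendar_week or ""

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    records: list[SievingRecord] = []
    for key in sorted(groups):
        passing_area = 0.0
        total_area = 0.0
        for inst in groups[key]:
            # pass/fail logic written out here, independent of quality_metrics;
            # the geometric primitives (shoelace area, min rectangle) are shared
            rect = inst.to_shapely().minimum_rotated_rectangle
            coords = np.asarray(rect.exterior.coords)
            e1 = float(np.hypot(*(coords[1] - coords[0])))
            e2 = float(np.hypot(*(coords[2] - coords[1])))
            minor_mm = min(e1, e2) / cal.px_per_mm
            area = polygon_area(inst.polygon)
            total_area += area
            if minor_mm < aperture_mm:
                passing_area += area
        csps = 100.0 * passing_area / total_area if total_area > 0 else 0.0
        if noise_sd > 0:
            csps += rng.normal(0.0, noise_sd)
        records.append(
            SievingRecord(
                sample_id=key,
                calendar_week=weeks[key],
                csps_percent=float(np.clip(csps, 0.0, 100.0)),
            )
        )
    return records
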