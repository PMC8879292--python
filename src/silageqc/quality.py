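"""Physically grounded crop-quality rules.

Three rules connect image annotations to forage quality:

* a minimum-size filter — fragments whose longest axis is under 2 mm (the
  1 mm-radius annotation indicator's diameter) are too small to annotate
  reliably and are excluded;
* the Corn Silage Processing Score (CSPS) — the percentage of kernel-fragment
  material that would pass a 4.75 mm sieve, estimated from polygon geometry
  with the minor axis (smallest cross-section) as the sieve measure and
  projected area as the mass proxy;
* the overlength rule for stover — a particle is overlength when its major
  axis exceeds 1.5 x the Theoretical Length of Cut.

Boundary conventions: sieve pass is strict ``<`` the aperture, overlength is
strict ``>`` the threshold, and the minimum-size keep is ``>=`` 2 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import math

import pandas as pd

from .core import AnnotationSet, Calibration, Instance, STOVER_LABELS, shape_summary

__all__ = [
    "QualityEstimate",
    "OverlengthRule",
    "min_size_filter",
    "sieve_pass",
    "estimate_csps",
    "overlength_threshold",
    "classify_overlength",
    "overlength_report",
]

logger = logging.getLogger(__name__)

SieveMeasure = Literal["minor_axis", "major_axis", "equivalent_diameter"]


@dataclass(frozen=True)
class QualityEstimate:
    sample_id: str
    calendar_week: str
    csps_percent: Optional[float]
    n_fragments: int
    n_passing: int
    weighting: Literal["area", "count"]

    def __post_init__(self) -> None:
        if self.csps_percent is not None and not 0.0 <= self.csps_percent <= 100.0:
            raise ValueError(f"csps_percent {self.csps_percent} outside [0, 100]")
        if self.n_passing > self.n_fragments:
            raise ValueError("n_passing exceeds n_fragments")


@dataclass(frozen=True)
class OverlengthRule:
    tloc_mm: float
    factor: float = 1.5

    @property
    def threshold_mm(self) -> float:
        return self.factor * self.tloc_mm


def overlength_threshold(tloc_mm: float, factor: float = 1.5) -> OverlengthRule:
    """Overlength size threshold for a chop length: ``factor * tloc_mm`` mm.

    At the default factor, silage cut at 4 mm has a 6 mm threshold —
    particles longer than that count as overlength.
    """
    if tloc_mm <= 0 or factor <= 0:
        raise ValueError("tloc_mm and factor must be positive")
    return OverlengthRule(tloc_mm=tloc_mm, factor=factor)


def classify_overlength(
    inst: Instance, rule: OverlengthRule, cal: Calibration
) -> bool:
    """True iff the particle's major axis strictly exceeds the threshold."""
    return shape_summary(inst, cal).major_axis_mm > rule.threshold_mm


def min_size_filter(
    aset: AnnotationSet, cal: Calibration, min_major_mm: float = 2.0
) -> AnnotationSet:
    """Drop instances whose major axis is below ``min_major_mm`` (keep >=).

    The default 2 mm is the diameter of the 1 mm-radius minimum-size
    indicator shown to annotators.  Removed ids are logged.
    """
    if min_major_mm <= 0:
        raise ValueError(f"min_major_mm must be positive, got {min_major_mm}")
    removed = [
        i.instance_id
        for i in aset.instances
        if shape_summary(i, cal).major_axis_mm < min_major_mm
    ]
    if removed:
        logger.info("min_size_filter removed %d instances: %s", len(removed), removed)
    kept = set(i.instance_id for i in aset.instances) - set(removed)
    return aset.filter_instances(lambda i: i.instance_id in kept)


def _sieve_measure_mm(inst: Instance, cal: Calibration, measure: SieveMeasure) -> float:
    ss = shape_summary(inst, cal)
    if measure == "minor_axis":
        return ss.minor_axis_mm
    if measure == "major_axis":
        return ss.major_axis_mm
    if measure == "equivalent_diameter":
        return 2.0 * math.sqrt(ss.area_mm2 / math.pi)
    raise ValueError(f"unknown sieve measure {measure!r}")


def sieve_pass(
    inst: Instance,
    cal: Calibration,
    aperture_mm: float = 4.75,
    measure: SieveMeasure = "minor_axis",
) -> bool:
    """True iff the instance would pass the sieve (measure strictly below the
    aperture).  A particle passes when its smallest cross-section fits, so
    the minor axis is the default measure."""
    return _sieve_measure_mm(inst, cal, measure) < aperture_mm


def estimate_csps(
    aset: AnnotationSet,
    cal: Calibration,
    aperture_mm: float = 4.75,
    weighting: Literal["area", "count"] = "area",
    measure: SieveMeasure = "minor_axis",
    sample_id: str = "",
    calendar_week: str = "",
) -> QualityEstimate:
    """Estimate the Corn Silage Processing Score from kernel-fragment
    polygons.

    Area weighting (default) treats projected polygon area as the proxy for
    mass: CSPS = 100 x passing area / total area.  Count weighting reports
    the plain fraction of passing fragments.  An empty set yields an absent
    value with a warning, never 0.
    """
    non_kernel = [i.instance_id for i in aset.instances if i.label != "kernel_fragment"]
    if non_kernel:
        raise ValueError(
            f"estimate_csps expects kernel fragments only; non-kernel instances: "
            f"{non_kernel}"
        )
    n_fragments = len(aset.instances)
    if n_fragments == 0:
        logger.warning("estimate_csps: empty fragment set for %r", sample_id)
        return QualityEstimate(
            sample_id=sample_id,
            calendar_week=calendar_week,
            csps_percent=None,
            n_fragments=0,
            n_passing=0,
            weighting=weighting,
        )
    passing_area = 0.0
    total_area = 0.0
    n_passing = 0
    for inst in aset.instances:
        # px^2 weights: the pass fraction is unit-free, and raw pixel areas
        # avoid a needless unit conversion inside the running sums
        area = shape_summary(inst, cal).area_px2
        total_area += area
        if sieve_pass(inst, cal, aperture_mm=aperture_mm, measure=measure):
            passing_area += area
            n_passing += 1
    if weighting == "area":
        csps = 100.0 * passing_area / total_area
    elif weighting == "count":
        csps = 100.0 * n_passing / n_fragments
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    csps = min(100.0, max(0.0, csps))  # guard float round-off at the ends
    return QualityEstimate(
        sample_id=sample_id,
        calendar_week=calendar_week,
        csps_percent=float(csps),
        n_fragments=n_fragments,
        n_passing=n_passing,
        weighting=weighting,
    )


def estimate_csps_per_sample(
    aset: AnnotationSet,
    cal: Calibration,
    aperture_mm: float = 4.75,
    weighting: Literal["area", "count"] = "area",
    measure: SieveMeasure = "minor_axis",
    group_by: Literal["image", "sequence"] = "image",
) -> list[QualityEstimate]:
    """CSPS estimate per sample group (image or harvest sequence)."""
    keys = sorted(
        {
            rec.image_id if group_by == "image" else rec.meta.sequence_id
            for rec in aset.images.values()
        }
    )
    out = []
    for key in keys:
        members = {
            rec.image_id
            for rec in aset.images.values()
            if (rec.image_id if group_by == "image" else rec.meta.sequence_id) == key
        }
        week = next(
            (
                aset.images[m].meta.calendar_week or ""
                for m in sorted(members)
            ),
            "",
        )
        sub = AnnotationSet(
            source_id=aset.source_id,
            images={m: aset.images[m] for m in members},
            instances=[
                i
                for i in aset.instances
                if i.image_id in members and i.label == "kernel_fragment"
            ],
        )
        out.append(
            estimate_csps(
                sub,
                cal,
                aperture_mm=aperture_mm,
                weighting=weighting,
                measure=measure,
                sample_id=key,
                calendar_week=week,
            )
        )
    return out


def overlength_report(aset: AnnotationSet, cal: Calibration) -> pd.DataFrame:
    """Per-TLOC overlength statistics: images, instances, per-class counts,
    average size, and average major/minor axes (delegates to the dataset
    statistics machinery)."""
    from .stats import summarize

    stover = aset.filter_instances(lambda i: i.label in STOVER_LABELS)
    return summarize(stover, group_by=("tloc_mm",))
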