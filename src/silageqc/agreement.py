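"""Inter- and intra-annotator agreement on instance annotations.

Two annotators "agree" on an instance when their polygons overlap with
Intersection-over-Union above 0.5.  Instances are matched one-to-one
(greedy by descending IoU), overlap counts tallied, and Cohen's Kappa
computed over a unit construction that turns the two instance sets into
paired annotated / not-annotated ratings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .core import AnnotationSet, Instance, polygon_iou

__all__ = [
    "MatchResult",
    "KappaReport",
    "match_instances",
    "overlap_counts",
    "cohen_kappa",
    "pairwise_agreement_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[tuple[str, str, float], ...]
    unmatched_a: tuple[str, ...]
    unmatched_b: tuple[str, ...]
    iou_threshold: float
    #: per shared image: (n pairs, n unmatched A, n unmatched B)
    per_image: Mapping[str, tuple[int, int, int]]


def _shared_images(a: AnnotationSet, b: AnnotationSet) -> list[str]:
    shared = sorted(set(a.images) & set(b.images))
    if set(a.images) != set(b.images):
        warnings.warn(
            f"image sets differ between {a.source_id!r} and {b.source_id!r}; "
            f"restricting to the {len(shared)} shared images",
            stacklevel=3,
        )
    return shared


def match_instances(
    a: AnnotationSet,
    b: AnnotationSet,
    iou_threshold: float = 0.5,
    class_aware: bool = True,
    method: Literal["greedy", "optimal"] = "greedy",
) -> MatchResult:
    """One-to-one correspondence between two instance sets.

    Candidate pairs are same-image (and same-class when ``class_aware``) with
    IoU strictly above the threshold.  The default greedy selection takes
    pairs by descending IoU, ties broken by the smaller A id then B id;
    ``optimal`` runs a maximum-cardinality/maximum-IoU assignment instead,
    for verification.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    shared = _shared_images(a, b)

    pairs: list[tuple[str, str, float]] = []
    unmatched_a: list[str] = []
    unmatched_b: list[str] = []
    per_image: dict[str, tuple[int, int, int]] = {}
    for image_id in shared:
        insts_a = sorted(a.instances_in(image_id), key=lambda i: i.instance_id)
        insts_b = sorted(b.instances_in(image_id), key=lambda i: i.instance_id)
        cand: list[tuple[float, str, str]] = []
        iou_of: dict[tuple[str, str], float] = {}
        for ia in insts_a:
            for ib in insts_b:
                if class_aware and ia.label != ib.label:
                    continue
                iou = polygon_iou(ia.polygon, ib.polygon)
                if iou > iou_threshold:
                    cand.append((iou, ia.instance_id, ib.instance_id))
                    iou_of[(ia.instance_id, ib.instance_id)] = iou

        if method == "greedy":
            cand.sort(key=lambda t: (-t[0], t[1], t[2]))
            taken_a: set[str] = set()
            taken_b: set[str] = set()
            img_pairs = []
            for iou, ida, idb in cand:
                if ida in taken_a or idb in taken_b:
                    continue
                taken_a.add(ida)
                taken_b.add(idb)
                img_pairs.append((ida, idb, iou))
        elif method == "optimal":
            img_pairs = _optimal_assignment(insts_a, insts_b, iou_of)
            taken_a = {p[0] for p in img_pairs}
            taken_b = {p[1] for p in img_pairs}
        else:
            raise ValueError(f"unknown method {method!r}")

        img_un_a = [i.instance_id for i in insts_a if i.instance_id not in taken_a]
        img_un_b = [i.instance_id for i in insts_b if i.instance_id not in taken_b]
        pairs.extend(img_pairs)
        unmatched_a.extend(img_un_a)
        unmatched_b.extend(img_un_b)
        per_image[image_id] = (len(img_pairs), len(img_un_a), len(img_un_b))

    return MatchResult(
        pairs=tuple(pairs),
        unmatched_a=tuple(unmatched_a),
        unmatched_b=tuple(unmatched_b),
        iou_threshold=iou_threshold,
        per_image=per_image,
    )


def _optimal_assignment(
    insts_a: Sequence[Instance],
    insts_b: Sequence[Instance],
    iou_of: Mapping[tuple[str, str], float],
) -> list[tuple[str, str, float]]:
    """Maximum-cardinality (then maximum total IoU) one-to-one assignment."""
    from scipy.optimize import linear_sum_assignment

    if not insts_a or not insts_b or not iou_of:
        return []
    ids_a = [i.instance_id for i in insts_a]
    ids_b = [i.instance_id for i in insts_b]
    # large constant rewards cardinality first, IoU second
    cost = np.zeros((len(ids_a), len(ids_b)))
    for (ida, idb), iou in iou_of.items():
        cost[ids_a.index(ida), ids_b.index(idb)] = 10.0 + iou
    ri, ci = linear_sum_assignment(-cost)
    out = []
    for r, c in zip(ri, ci):
        if cost[r, c] > 0:
            out.append((ids_a[r], ids_b[c], cost[r, c] - 10.0))
    return out


def overlap_counts(match: MatchResult) -> tuple[int, int, int]:
    """(n_A, n_B, n_agreed) from a match result."""
    n_agreed = len(match.pairs)
    n_a = n_agreed + len(match.unmatched_a)
    n_b = n_agreed + len(match.unmatched_b)
    return n_a, n_b, n_agreed


@dataclass(frozen=True)
class KappaReport:
    annotator_pair: tuple[str, str]
    sequence_id: str
    kappa_raw: Optional[float]
    kappa_reported: Optional[float]
    n_a: int
    n_b: int
    n_agreed: int
    contingency: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False
    available: bool = True

    @classmethod
    def not_available(cls, pair, sequence_id) -> "KappaReport":
        return cls(
            annotator_pair=pair,
            sequence_id=sequence_id,
            kappa_raw=None,
            kappa_reported=None,
            n_a=0,
            n_b=0,
            n_agreed=0,
            contingency=((0, 0), (0, 0)),
            available=False,
        )


def cohen_kappa(
    a: AnnotationSet,
    b: AnnotationSet,
    iou_threshold: float = 0.5,
    class_aware: bool = True,
    background_budget: Optional[int] = None,
    sequence_id: str = "",
) -> KappaReport:
    """Cohen's Kappa between two annotators' instance sets.

    Rating units are the one-to-one match classes of the cross-annotator
    IoU>threshold graph (matched pair: rated annotated by both; unmatched
    instance: annotated by its owner only) plus per-image background
    pseudo-units rated not-annotated by both.  The background budget per
    image defaults to the maximum per-image unit count, so chance agreement
    is corrected against a common frame.  Negative kappa is clipped to 0 in
    the headline value; the raw value is retained.
    """
    shared = set(a.images) & set(b.images)
    if not shared:
        raise ValueError(
            f"no shared images between {a.source_id!r} and {b.source_id!r}"
        )
    match = match_instances(a, b, iou_threshold=iou_threshold, class_aware=class_aware)
    n_a, n_b, n_agreed = overlap_counts(match)

    units = {img: sum(c) for img, c in match.per_image.items()}
    budget = background_budget if background_budget is not None else (
        max(units.values()) if units else 0
    )
    n_background = sum(max(budget - u, 0) for u in units.values())

    both = len(match.pairs)
    a_only = len(match.unmatched_a)
    b_only = len(match.unmatched_b)
    neither = n_background
    n = both + a_only + b_only + neither
    contingency = ((both, a_only), (b_only, neither))

    if n == 0:
        return KappaReport(
            annotator_pair=(a.source_id, b.source_id),
            sequence_id=sequence_id,
            kappa_raw=None,
            kappa_reported=None,
            n_a=0,
            n_b=0,
            n_agreed=0,
            contingency=contingency,
            degenerate=True,
        )

    p_o = (both + neither) / n
    p_yes_a = (both + a_only) / n
    p_yes_b = (both + b_only) / n
    p_e = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
    degenerate = abs(1.0 - p_e) < 1e-12
    if degenerate:
        # both raters constant: full agreement -> 1, anything else -> 0
        kappa_raw = 1.0 if (a_only + b_only) == 0 else 0.0
        logger.warning(
            "degenerate chance agreement (P_e = 1) for pair (%s, %s)",
            a.source_id,
            b.source_id,
        )
    else:
        kappa_raw = (p_o - p_e) / (1.0 - p_e)
    return KappaReport(
        annotator_pair=(a.source_id, b.source_id),
        sequence_id=sequence_id,
        kappa_raw=float(kappa_raw),
        kappa_reported=float(max(0.0, kappa_raw)),
        n_a=n_a,
        n_b=n_b,
        n_agreed=n_agreed,
        contingency=contingency,
        degenerate=degenerate,
    )


def pairwise_agreement_report(
    sets: Mapping[tuple[str, str], AnnotationSet],
    iou_threshold: float = 0.5,
    class_aware: bool = True,
) -> list[KappaReport]:
    """Kappa for every ordered annotator pair within every sequence.

    ``sets`` maps (source_id, sequence_id) to the annotation set of that
    annotator on that sequence.  Missing annotator/sequence combinations
    (including pairs with no shared images) yield not-available reports, as
    real agreement tables print "na" cells.  Repeated sources under distinct
    sequence tags support intra-rater comparisons.
    """
    sources = sorted({src for src, _ in sets})
    sequences = sorted({seq for _, seq in sets})
    reports: list[KappaReport] = []
    for seq in sequences:
        for src_a in sources:
            for src_b in sources:
                if src_a == src_b:
                    continue
                pair = (src_a, src_b)
                sa = sets.get((src_a, seq))
                sb = sets.get((src_b, seq))
                if sa is None or sb is None or not (set(sa.images) & set(sb.images)):
                    reports.append(KappaReport.not_available(pair, seq))
                    continue
                reports.append(
                    cohen_kappa(
                        sa,
                        sb,
                        iou_threshold=iou_threshold,
                        class_aware=class_aware,
                        sequence_id=seq,
                    )
                )
    return reports
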