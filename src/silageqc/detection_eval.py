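"""COCO-standard detection evaluation, sieving correlation, and run
comparison.

The evaluator follows the COCO protocol: per class, detections are matched
greedily in descending score order to the unmatched ground-truth instance of
highest IoU at each threshold in 0.50:0.05:0.95; average precision is the
monotone-envelope precision sampled at 101 recall points, averaged over the
10 thresholds; average recall at k detections per image is the recall mean
over thresholds.  All metrics are reported on the 0-100 scale.  Segmentation
(polygon) IoU is the default, matching polygon annotations; box IoU is
available for bounding-box detectors.  No area-range breakdown and no crowd
regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnnotationSet, bbox_iou, polygon_iou
from .quality import QualityEstimate
from .synthetic import SievingRecord

__all__ = [
    "EvalResult",
    "CorrelationResult",
    "RunComparison",
    "evaluate_detections",
    "pearson_correlation",
    "compare_runs",
    "IOU_THRESHOLDS",
]

logger = logging.getLogger(__name__)

IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)
# i/100 gives the float nearest each decimal sample point; accumulating a
# 0.01 step drifts by an ulp at some points, which matters because sampled
# recalls are exact small-denominator rationals
RECALL_POINTS = np.array([i / 100 for i in range(101)])
AR_CAPS = (1, 10, 100)
METRICS = ("AP", "AP50", "AP75", "AR1", "AR10", "AR100")


@dataclass(frozen=True)
class EvalResult:
    """AP/AR metrics per class and overall, on the 0-100 scale."""

    per_class: Mapping[str, Mapping[str, float]]
    overall: Mapping[str, float]
    n_gt: Mapping[str, int]


def _pairwise_iou(gts, dets, mode: str) -> np.ndarray:
    fn = polygon_iou if mode == "segm" else bbox_iou
    out = np.zeros((len(dets), len(gts)))
    for d, det in enumerate(dets):
        for g, gt in enumerate(gts):
            out[d, g] = fn(det.polygon, gt.polygon)
    return out


def _ap_from_matches(tp_flags: np.ndarray, n_gt: int) -> float:
    """Exact 101-point interpolated AP from ordered TP/FP flags."""
    if n_gt == 0:
        return float("nan")
    if len(tp_flags) == 0:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~tp_flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # monotone envelope from the right
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    # precision at the first point with recall >= r, else 0
    idx = np.searchsorted(recall, RECALL_POINTS, side="left")
    sampled = np.where(idx < len(recall), precision[np.minimum(idx, len(recall) - 1)], 0.0)
    return float(sampled.mean())


def _match_class(
    gt_by_img: Mapping[str, list],
    det_order: Sequence[tuple[str, int]],
    ious: Mapping[str, np.ndarray],
    thr: float,
) -> np.ndarray:
    """Greedy COCO matching at one IoU threshold.

    ``det_order`` lists (image_id, det-local-index) in global score order;
    returns a TP flag per detection in that order.
    """
    flags = np.zeros(len(det_order), dtype=bool)
    taken: dict[str, set[int]] = {img: set() for img in gt_by_img}
    for k, (img, d) in enumerate(det_order):
        iou_row = ious[img][d]
        best_g = -1
        best_iou = thr  # must reach the threshold
        for g in range(iou_row.shape[0]):
            if g in taken[img]:
                continue
            if iou_row[g] >= best_iou and (
                best_g == -1 or iou_row[g] > best_iou
            ):
                best_iou = iou_row[g]
                best_g = g
        if best_g >= 0:
            taken[img].add(best_g)
            flags[k] = True
    return flags


def evaluate_detections(
    gt: AnnotationSet,
    det: AnnotationSet,
    iou_mode: Literal["segm", "bbox"] = "segm",
) -> EvalResult:
    """COCO AP/AR of scored detections against ground-truth annotations.

    Overall metrics are the mean of per-class values over classes with at
    least one ground-truth instance.
    """
    for inst in det.instances:
        if inst.score is None:
            raise ValueError(f"detection {inst.instance_id!r} has no score")
    gt_labels = {i.label for i in gt.instances}
    extra = {i.label for i in det.instances} - gt_labels
    if extra:
        raise ValueError(
            f"detection classes absent from the ground-truth taxonomy: {sorted(extra)}"
        )
    images = sorted(set(gt.images) | set(det.images))

    per_class: dict[str, dict[str, float]] = {}
    n_gt_per_class: dict[str, int] = {}
    for label in sorted(gt_labels):
        gt_by_img = {
            img: sorted(
                (i for i in gt.instances_in(img) if i.label == label),
                key=lambda i: i.instance_id,
            )
            for img in images
        }
        det_by_img = {
            img: sorted(
                (i for i in det.instances_in(img) if i.label == label),
                key=lambda i: (-i.score, i.instance_id),
            )
            for img in images
        }
        n_gt = sum(len(v) for v in gt_by_img.values())
        n_gt_per_class[label] = n_gt
        if n_gt == 0:
            continue
        ious = {
            img: _pairwise_iou(gt_by_img[img], det_by_img[img], iou_mode)
            for img in images
        }

        def _global_order(cap: Optional[int]) -> list[tuple[str, int]]:
            entries = []
            for img in images:
                dets = det_by_img[img][: cap if cap is not None else None]
                for d, inst in enumerate(dets):
                    entries.append((-inst.score, inst.instance_id, img, d))
            entries.sort()
            return [(img, d) for _, _, img, d in entries]

        order_all = _global_order(None)
        ap_per_thr = []
        recall_per_thr = {cap: [] for cap in AR_CAPS}
        for thr in IOU_THRESHOLDS:
            flags = _match_class(gt_by_img, order_all, ious, thr)
            ap_per_thr.append(_ap_from_matches(flags, n_gt))
            for cap in AR_CAPS:
                order_cap = _global_order(cap)
                cap_flags = _match_class(gt_by_img, order_cap, ious, thr)
                recall_per_thr[cap].append(cap_flags.sum() / n_gt)

        ap_arr = np.array(ap_per_thr)
        per_class[label] = {
            "AP": 100.0 * float(ap_arr.mean()),
            "AP50": 100.0 * float(ap_arr[0]),
            "AP75": 100.0 * float(ap_arr[5]),
            "AR1": 100.0 * float(np.mean(recall_per_thr[1])),
            "AR10": 100.0 * float(np.mean(recall_per_thr[10])),
            "AR100": 100.0 * float(np.mean(recall_per_thr[100])),
        }

    if per_class:
        overall = {
            m: float(np.mean([v[m] for v in per_class.values()])) for m in METRICS
        }
    else:
        overall = {m: float("nan") for m in METRICS}
    return EvalResult(per_class=per_class, overall=overall, n_gt=n_gt_per_class)


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    pcc: Optional[float]
    n: int


def pearson_correlation(
    estimates: Sequence[QualityEstimate],
    sieve: Sequence[SievingRecord],
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Pearson correlation of image-derived CSPS against sieved CSPS.

    Samples are paired on ``sample_id``; one result per calendar week plus a
    pooled result over all weeks.  Groups with zero variance in either
    variable report an absent coefficient with a warning.
    """
    est_by_id = {e.sample_id: e for e in estimates if e.csps_percent is not None}
    sieve_by_id = {s.sample_id: s for s in sieve}
    unpaired = sorted(set(est_by_id) ^ set(sieve_by_id))
    if unpaired:
        raise ValueError(f"unpaired sample ids: {unpaired}")

    pairs = pd.DataFrame(
        {
            "week": [sieve_by_id[k].calendar_week for k in sorted(est_by_id)],
            "est": [est_by_id[k].csps_percent for k in sorted(est_by_id)],
            "phys": [sieve_by_id[k].csps_percent for k in sorted(est_by_id)],
        }
    )
    weeks = sorted(pairs["week"].unique())
    groups = [(w, pairs[pairs["week"] == w]) for w in weeks]
    if len(weeks) > 1:
        groups.append(("+".join(weeks), pairs))

    out: list[CorrelationResult] = []
    for name, sub in groups:
        n = len(sub)
        if n < min_n:
            raise ValueError(f"group {name!r} has only {n} paired samples (< {min_n})")
        if sub["est"].std() == 0 or sub["phys"].std() == 0:
            warnings.warn(f"group {name!r}: zero variance, correlation undefined")
            out.append(CorrelationResult(group=name, pcc=None, n=n))
            continue
        r = float(sps.pearsonr(sub["est"], sub["phys"]).statistic)
        out.append(CorrelationResult(group=name, pcc=r, n=n))
    return out


@dataclass(frozen=True)
class RunComparison:
    run_id: str
    baseline_id: str
    deltas_pp: Mapping[str, float]  # run - baseline, percentage points
    ratios: Mapping[str, float]  # run / baseline where baseline > 0
    best_for: tuple[str, ...] = ()


def compare_runs(
    results: pd.DataFrame, baseline: str
) -> list[RunComparison]:
    """Metric deltas of every run against a baseline run.

    ``results`` is a run-by-metric table (index = run id); metrics are on the
    0-100 scale so deltas read as percentage points.  Diverged runs (NaN
    metrics) propagate NaN deltas.  The best run per metric is flagged.
    """
    if baseline not in results.index:
        raise ValueError(f"baseline run {baseline!r} not in results table")
    base = results.loc[baseline]
    best = {m: results[m].idxmax() for m in results.columns if results[m].notna().any()}
    out = []
    for run_id, row in results.iterrows():
        if run_id == baseline:
            continue
        deltas = {m: float(row[m] - base[m]) for m in results.columns}
        ratios = {
            m: float(row[m] / base[m]) for m in results.columns if base[m] and base[m] > 0
        }
        out.append(
            RunComparison(
                run_id=str(run_id),
                baseline_id=baseline,
                deltas_pp=deltas,
                ratios=ratios,
                best_for=tuple(m for m, b in best.items() if b == run_id),
            )
        )
    return out
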