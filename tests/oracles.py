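"""Independent brute-force oracles the implementation is checked against.

Each oracle restates its quantity from first principles with naive loops, so
agreement with the package is a genuine cross-check rather than a repeated
computation: rotating calipers for the minimum-area rectangle, point-grid
rasterization for polygon IoU, prefix-enumeration PR integration for the
COCO metrics, a direct 2x2 contingency for Cohen's kappa, and a
maximum-cardinality assignment for instance matching.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

IOU_THRESHOLDS = [round(0.5 + 0.05 * i, 2) for i in range(10)]
RECALL_POINTS = [i / 100 for i in range(101)]


def rotating_calipers_rect(points: np.ndarray) -> tuple[float, float]:
    """(major, minor) side lengths of the minimum-area enclosing rectangle.

    Enumerates every hull-edge orientation; the optimal rectangle has a side
    collinear with a hull edge.
    """
    hull = ShapelyPolygon(points).convex_hull
    verts = np.asarray(hull.exterior.coords[:-1])
    best = None
    for i in range(len(verts)):
        edge = verts[(i + 1) % len(verts)] - verts[i]
        angle = np.arctan2(edge[1], edge[0])
        c, s = np.cos(-angle), np.sin(-angle)
        rot = points @ np.array([[c, -s], [s, c]]).T
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, max(w, h), min(w, h))
    return best[1], best[2]


def raster_iou(a: np.ndarray, b: np.ndarray, n: int = 500) -> float:
    """IoU by counting grid cell centres inside each polygon."""
    pa, pb = ShapelyPolygon(a), ShapelyPolygon(b)
    x0 = min(a[:, 0].min(), b[:, 0].min())
    x1 = max(a[:, 0].max(), b[:, 0].max())
    y0 = min(a[:, 1].min(), b[:, 1].min())
    y1 = max(a[:, 1].max(), b[:, 1].max())
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    gx, gy = np.meshgrid(xs, ys)
    in_a = shapely.contains_xy(pa, gx.ravel(), gy.ravel())
    in_b = shapely.contains_xy(pb, gx.ravel(), gy.ravel())
    union = np.logical_or(in_a, in_b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(in_a, in_b).sum() / union)


def hand_cohen_kappa(both: int, a_only: int, b_only: int, neither: int) -> float:
    """Cohen's kappa straight from the 2x2 contingency definition."""
    n = both + a_only + b_only + neither
    p_o = (both + neither) / n
    p_yes_a = (both + a_only) / n
    p_yes_b = (both + b_only) / n
    p_e = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
    return (p_o - p_e) / (1 - p_e)


def max_cardinality_matching(iou: np.ndarray, threshold: float) -> int:
    """Maximum number of one-to-one pairs with IoU above the threshold
    (Hungarian on a 0/1 reward)."""
    from scipy.optimize import linear_sum_assignment

    if iou.size == 0:
        return 0
    reward = (iou > threshold).astype(float)
    ri, ci = linear_sum_assignment(-reward)
    return int(reward[ri, ci].sum())


def _iou_fn(mode: str):
    from silageqc.core import bbox_iou, polygon_iou

    return polygon_iou if mode == "segm" else bbox_iou


def coco_oracle(gt, det, iou_mode: str = "segm") -> dict:
    """Brute-force COCO metrics for one small scene collection.

    Matches detections in descending score order with explicit loops; AP is
    the interpolated precision max over *prefixes* whose recall reaches each
    of the 101 sample points — an independent restatement of the
    precision-envelope construction.
    """
    iou_of = _iou_fn(iou_mode)
    labels = sorted({i.label for i in gt.instances})
    per_class = {}
    for label in labels:
        gts = {
            img: sorted(
                [i for i in gt.instances_in(img) if i.label == label],
                key=lambda i: i.instance_id,
            )
            for img in gt.images
        }
        n_gt = sum(len(v) for v in gts.values())
        if n_gt == 0:
            continue
        all_dets = sorted(
            [i for i in det.instances if i.label == label],
            key=lambda i: (-i.score, i.instance_id),
        )

        def run_matching(dets, thr):
            taken = {img: [False] * len(gts[img]) for img in gts}
            flags = []
            for d in dets:
                cand = gts.get(d.image_id, [])
                best, best_iou = -1, thr
                for g, ginst in enumerate(cand):
                    if taken[d.image_id][g]:
                        continue
                    v = iou_of(d.polygon, ginst.polygon)
                    if v >= best_iou and (best == -1 or v > best_iou):
                        best_iou, best = v, g
                if best >= 0:
                    taken[d.image_id][best] = True
                    flags.append(True)
                else:
                    flags.append(False)
            return flags

        ap_per_thr = []
        for thr in IOU_THRESHOLDS:
            flags = run_matching(all_dets, thr)
            # precision/recall at every prefix length
            prefix = []
            tp = 0
            for k, f in enumerate(flags, start=1):
                tp += int(f)
                prefix.append((tp / n_gt, tp / k))
            ap = 0.0
            for r in RECALL_POINTS:
                best_p = 0.0
                for rec, prec in prefix:
                    if rec >= r and prec > best_p:
                        best_p = prec
                ap += best_p
            ap_per_thr.append(ap / 101)

        def recall_capped(cap):
            per_img = {
                img: sorted(
                    [i for i in det.instances_in(img) if i.label == label],
                    key=lambda i: (-i.score, i.instance_id),
                )[:cap]
                for img in gt.images
            }
            dets = sorted(
                [d for lst in per_img.values() for d in lst],
                key=lambda i: (-i.score, i.instance_id),
            )
            vals = []
            for thr in IOU_THRESHOLDS:
                flags = run_matching(dets, thr)
                vals.append(sum(flags) / n_gt)
            return 100.0 * sum(vals) / len(vals)

        per_class[label] = {
            "AP": 100.0 * sum(ap_per_thr) / len(ap_per_thr),
            "AP50": 100.0 * ap_per_thr[0],
            "AP75": 100.0 * ap_per_thr[5],
            "AR1": recall_capped(1),
            "AR10": recall_capped(10),
            "AR100": recall_capped(100),
        }
    overall = {
        m: sum(v[m] for v in per_class.values()) / len(per_class)
        for m in ("AP", "AP50", "AP75", "AR1", "AR10", "AR100")
    }
    return {"per_class": per_class, "overall": overall}
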