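"""Dataset-descriptive statistics: per-setting counts, sizes, and
machine-setting trend summaries.

The tables mirror the published layout for harvest annotation statistics:
one row per machine-setting group (Processor Gap x Theoretical Length of
Cut), or per annotator/sequence, plus a Total row.  The instances-per-image
ratio is defined as total instances / total images, rounded half-even to two
decimals; where printed source tables disagree with that arithmetic the
discrepancy is documented rather than emulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import LABELS, AnnotationSet, shape_summary

__all__ = ["insts_per_img", "summarize", "class_counts", "trend_report", "TrendReport"]

logger = logging.getLogger(__name__)


def insts_per_img(instances: int, images: int) -> Optional[float]:
    """Average instances per image, rounded half-even to 2 decimals.

    Returns None for an empty image set (an undefined ratio is reported as
    absent, never as zero).
    """
    if images == 0:
        return None
    ratio = Decimal(instances) / Decimal(images)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


_GROUP_FIELDS = {
    "pg_mm": lambda rec: rec.meta.pg_mm,
    "tloc_mm": lambda rec: rec.meta.tloc_mm,
    "year": lambda rec: rec.meta.year,
    "sequence_id": lambda rec: rec.meta.sequence_id,
    "calendar_week": lambda rec: rec.meta.calendar_week,
}


def summarize(
    aset: AnnotationSet,
    group_by: Sequence[str] = ("pg_mm", "tloc_mm"),
    axis_mode: str = "min_rect",
) -> pd.DataFrame:
    """One statistics row per metadata group plus a Total row.

    Columns: the grouping keys, n_sequences, images, instances,
    insts_per_img, avg_size_px2, median_size_px2, avg_major_axis_mm,
    avg_minor_axis_mm, and one count column per class label.
    """
    for key in group_by:
        if key not in _GROUP_FIELDS:
            raise ValueError(f"unknown group_by key {key!r}")
    missing = [
        rec.image_id
        for rec in aset.images.values()
        if any(_GROUP_FIELDS[k](rec) is None for k in group_by)
    ]
    if missing:
        raise ValueError(f"images missing group metadata: {missing}")

    img_rows = []
    for rec in aset.images.values():
        img_rows.append(
            {"image_id": rec.image_id, "sequence_id": rec.meta.sequence_id}
            | {k: _GROUP_FIELDS[k](rec) for k in group_by}
        )
    img_cols = ["image_id", "sequence_id"] + [
        k for k in group_by if k not in ("image_id", "sequence_id")
    ]
    img_df = pd.DataFrame(img_rows, columns=img_cols)

    inst_rows = []
    for inst in aset.instances:
        rec = aset.images[inst.image_id]
        ss = shape_summary(inst, rec.calibration, axis_mode=axis_mode)
        inst_rows.append(
            {
                "image_id": inst.image_id,
                "label": inst.label,
                "area_px2": ss.area_px2,
                "major_mm": ss.major_axis_mm,
                "minor_mm": ss.minor_axis_mm,
            }
        )
    inst_df = pd.DataFrame(
        inst_rows, columns=["image_id", "label", "area_px2", "major_mm", "minor_mm"]
    )

    def _row(key_vals, sub_imgs: pd.DataFrame, sub_insts: pd.DataFrame) -> dict:
        n_img = len(sub_imgs)
        n_inst = len(sub_insts)
        row = dict(key_vals)
        row.update(
            n_sequences=sub_imgs["sequence_id"].nunique(),
            images=n_img,
            instances=n_inst,
            insts_per_img=insts_per_img(n_inst, n_img),
            avg_size_px2=float(sub_insts["area_px2"].mean()) if n_inst else np.nan,
            median_size_px2=float(sub_insts["area_px2"].median()) if n_inst else np.nan,
            avg_major_axis_mm=float(sub_insts["major_mm"].mean()) if n_inst else np.nan,
            avg_minor_axis_mm=float(sub_insts["minor_mm"].mean()) if n_inst else np.nan,
        )
        counts = sub_insts["label"].value_counts()
        for label in LABELS:
            row[f"n_{label}"] = int(counts.get(label, 0))
        return row

    rows = []
    if len(img_df):
        for key_vals, sub_imgs in img_df.groupby(list(group_by), sort=True):
            if not isinstance(key_vals, tuple):
                key_vals = (key_vals,)
            if len(sub_imgs) == 0:
                logger.warning("group %s has zero images; omitted", key_vals)
                continue
            sub_insts = inst_df[inst_df["image_id"].isin(sub_imgs["image_id"])]
            rows.append(_row(dict(zip(group_by, key_vals)), sub_imgs, sub_insts))
    total = _row({k: "Total" for k in group_by}, img_df, inst_df)
    rows.append(total)
    return pd.DataFrame(rows)


def class_counts(sets: Sequence[AnnotationSet]) -> pd.DataFrame:
    """Label x source count table; column sums equal instance totals."""
    table = pd.DataFrame(0, index=list(LABELS), columns=[s.source_id for s in sets])
    for s in sets:
        for inst in s.instances:
            table.loc[inst.label, s.source_id] += 1
    return table


@dataclass(frozen=True)
class TrendReport:
    """Monotonicity of size and count statistics along a machine setting,
    one entry per stratum of the other setting."""

    along: str
    strata: dict  # stratum value -> dict of flags and Spearman statistics

    @property
    def all_monotone(self) -> bool:
        return all(
            s["size_non_decreasing"] and s["count_non_increasing"]
            for s in self.strata.values()
        )


def trend_report(
    rows: pd.DataFrame, along: str = "pg_mm", stratify_by: str = "tloc_mm"
) -> TrendReport:
    """Check the expected machine-setting trends in a summary table.

    A smaller Processor Gap should produce more and smaller fragments, so
    along PG the median size should be non-decreasing and instances per image
    non-increasing.  Spearman rank correlations quantify the trend; strata
    violating monotonicity are flagged (real harvests before the
    sanity-checked season often do violate it).
    """
    body = rows[rows[along] != "Total"]
    strata = {}
    for stratum, sub in body.groupby(stratify_by, sort=True):
        sub = sub.sort_values(along)
        sizes = sub["median_size_px2"].to_numpy(dtype=float)
        counts = sub["insts_per_img"].to_numpy(dtype=float)
        entry = {
            "n_levels": len(sub),
            "size_non_decreasing": bool(np.all(np.diff(sizes) >= 0)),
            "count_non_increasing": bool(np.all(np.diff(counts) <= 0)),
        }
        if len(sub) >= 3:
            x = sub[along].to_numpy(dtype=float)
            entry["spearman_size"] = float(sps.spearmanr(x, sizes).statistic)
            entry["spearman_count"] = float(sps.spearmanr(x, counts).statistic)
        else:
            entry["spearman_size"] = np.nan
            entry["spearman_count"] = np.nan
        strata[stratum] = entry
    return TrendReport(along=along, strata=strata)
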