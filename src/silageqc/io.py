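"""COCO-dialect readers and writers plus the sidecar metadata tables.

Annotations travel as standard COCO instance-segmentation JSON with polygon
``segmentation`` entries (flat ``[x0, y0, x1, y1, ...]`` lists); detections as
the COCO results dialect (a list of ``{image_id, category_id, segmentation,
score}``).  Run-length-encoded masks are not supported.  Harvest metadata —
which COCO has no slot for — rides in a sidecar CSV keyed by image id.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .core import (
    LABELS,
    AnnotationSet,
    Calibration,
    HarvestMeta,
    ImageRecord,
    Instance,
)

__all__ = [
    "load_annotations",
    "save_annotations",
    "load_detections",
    "save_detections",
    "load_meta_table",
    "save_meta_table",
    "load_sieving_csv",
    "save_sieving_csv",
]

CATEGORY_IDS = {name: i + 1 for i, name in enumerate(LABELS)}
CATEGORY_NAMES = {i: name for name, i in CATEGORY_IDS.items()}


def _flat_to_vertices(seg: list[float]) -> list[list[float]]:
    if len(seg) % 2 != 0:
        raise ValueError("segmentation list has odd length")
    return [[seg[i], seg[i + 1]] for i in range(0, len(seg), 2)]


def _segmentation_ring(ann: Mapping, where: str) -> list[float]:
    seg = ann.get("segmentation")
    if isinstance(seg, Mapping) or (
        isinstance(seg, list) and seg and isinstance(seg[0], Mapping)
    ):
        raise ValueError(f"{where}: RLE segmentations are not supported")
    if isinstance(seg, list) and seg and isinstance(seg[0], list):
        if len(seg) > 1:
            raise ValueError(f"{where}: multi-polygon segmentations are not supported")
        seg = seg[0]
    if not isinstance(seg, list) or not seg:
        raise ValueError(f"{where}: missing or malformed segmentation")
    return seg


def _category_label(cat_id: int, names: Mapping[int, str], where: str) -> str:
    if cat_id not in names:
        raise ValueError(f"{where}: unknown category id {cat_id}")
    name = names[cat_id]
    if name not in LABELS:
        raise ValueError(f"{where}: category {name!r} outside the label taxonomy")
    return name


def load_annotations(
    path: str | Path,
    calibration: Calibration,
    meta_table: Optional[Mapping[str, HarvestMeta]] = None,
    source_id: Optional[str] = None,
    default_meta: Optional[HarvestMeta] = None,
) -> AnnotationSet:
    """Read a COCO instance-segmentation file into an :class:`AnnotationSet`.

    ``meta_table`` maps image ids to harvest metadata; images absent from it
    fall back to ``default_meta`` or raise.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON: {exc}") from exc

    cat_names = {
        int(c["id"]): str(c["name"]) for c in doc.get("categories", [])
    } or dict(CATEGORY_NAMES)

    images: dict[str, ImageRecord] = {}
    for img in doc.get("images", []):
        image_id = str(img["id"])
        meta = None
        if meta_table is not None:
            meta = meta_table.get(image_id)
        if meta is None:
            meta = default_meta
        if meta is None:
            raise ValueError(f"{path}: no harvest metadata for image {image_id!r}")
        images[image_id] = ImageRecord(
            image_id=image_id,
            width_px=int(img["width"]),
            height_px=int(img["height"]),
            calibration=calibration,
            meta=meta,
        )

    instances: list[Instance] = []
    bad: list[str] = []
    for ann in doc.get("annotations", []):
        where = f"{path}: annotation id {ann.get('id')!r}"
        seg = _segmentation_ring(ann, where)
        label = _category_label(int(ann["category_id"]), cat_names, where)
        try:
            instances.append(
                Instance(
                    instance_id=str(ann["id"]),
                    image_id=str(ann["image_id"]),
                    label=label,
                    polygon=_flat_to_vertices(seg),
                )
            )
        except ValueError:
            bad.append(str(ann.get("id")))
    if bad:
        raise ValueError(f"{path}: invalid polygons for annotation ids {bad}")

    return AnnotationSet(
        source_id=source_id or doc.get("info", {}).get("source_id", path.stem),
        images=images,
        instances=instances,
    )


def save_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as COCO instance-segmentation JSON."""
    doc = {
        "info": {"source_id": aset.source_id},
        "images": [
            {"id": rec.image_id, "width": rec.width_px, "height": rec.height_px}
            for rec in aset.images.values()
        ],
        "categories": [
            {"id": cid, "name": name} for name, cid in CATEGORY_IDS.items()
        ],
        "annotations": [
            {
                "id": inst.instance_id,
                "image_id": inst.image_id,
                "category_id": CATEGORY_IDS[inst.label],
                "segmentation": [inst.polygon.ravel().tolist()],
                "iscrowd": 0,
            }
            for inst in aset.instances
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_detections(
    path: str | Path,
    calibration: Calibration,
    meta_table: Optional[Mapping[str, HarvestMeta]] = None,
    images: Optional[Iterable[ImageRecord]] = None,
    source_id: str = "detector",
    default_meta: Optional[HarvestMeta] = None,
) -> AnnotationSet:
    """Read a COCO results file (scored instances) into an AnnotationSet.

    The results dialect carries no image table, so image records are taken
    from ``images`` when given and otherwise synthesised from polygon extents.
    Every record must carry a score in [0, 1].
    """
    path = Path(path)
    try:
        entries = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(entries, list):
        raise ValueError(f"{path}: detection results must be a JSON list")

    image_index: dict[str, ImageRecord] = (
        {rec.image_id: rec for rec in images} if images is not None else {}
    )
    instances: list[Instance] = []
    for k, ann in enumerate(entries):
        where = f"{path}: result #{k}"
        if "score" not in ann:
            raise ValueError(f"{where}: missing score")
        seg = _segmentation_ring(ann, where)
        label = _category_label(int(ann["category_id"]), CATEGORY_NAMES, where)
        inst = Instance(
            instance_id=str(ann.get("id", k)),
            image_id=str(ann["image_id"]),
            label=label,
            polygon=_flat_to_vertices(seg),
            score=float(ann["score"]),
        )
        instances.append(inst)
        if inst.image_id not in image_index:
            meta = (meta_table or {}).get(inst.image_id) or default_meta
            if meta is None:
                raise ValueError(
                    f"{where}: no image record or metadata for image "
                    f"{inst.image_id!r}"
                )
            hi = inst.polygon.max(axis=0)
            image_index[inst.image_id] = ImageRecord(
                image_id=inst.image_id,
                width_px=int(hi[0]) + 1,
                height_px=int(hi[1]) + 1,
                calibration=calibration,
                meta=meta,
            )

    return AnnotationSet(source_id=source_id, images=image_index, instances=instances)


def save_detections(aset: AnnotationSet, path: str | Path) -> None:
    """Write scored instances as a COCO results file."""
    entries = []
    for inst in aset.instances:
        if inst.score is None:
            raise ValueError(f"instance {inst.instance_id!r} has no score")
        entries.append(
            {
                "id": inst.instance_id,
                "image_id": inst.image_id,
                "category_id": CATEGORY_IDS[inst.label],
                "segmentation": [inst.polygon.ravel().tolist()],
                "score": inst.score,
            }
        )
    Path(path).write_text(json.dumps(entries))


META_COLUMNS = [
    "image_id",
    "year",
    "sequence_id",
    "pg_mm",
    "tloc_mm",
    "calendar_week",
    "px_per_mm",
]


def load_meta_table(path: str | Path) -> tuple[dict[str, HarvestMeta], Calibration]:
    """Read the sidecar metadata CSV.

    Returns the image-id → metadata mapping and the (single) calibration; the
    file must not mix resolutions.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "sequence_id": str})
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    res = df["px_per_mm"].unique()
    if len(res) != 1:
        raise ValueError(f"{path}: mixed px_per_mm values {res.tolist()}")
    meta = {
        row.image_id: HarvestMeta(
            year=int(row.year),
            sequence_id=str(row.sequence_id),
            pg_mm=float(row.pg_mm),
            tloc_mm=float(row.tloc_mm),
            calendar_week=None if pd.isna(row.calendar_week) else str(row.calendar_week),
        )
        for row in df.itertuples()
    }
    return meta, Calibration(px_per_mm=float(res[0]))


def save_meta_table(aset: AnnotationSet, path: str | Path) -> None:
    rows = [
        {
            "image_id": rec.image_id,
            "year": rec.meta.year,
            "sequence_id": rec.meta.sequence_id,
            "pg_mm": rec.meta.pg_mm,
            "tloc_mm": rec.meta.tloc_mm,
            "calendar_week": rec.meta.calendar_week,
            "px_per_mm": rec.calibration.px_per_mm,
        }
        for rec in aset.images.values()
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, index=False)


def load_sieving_csv(path: str | Path) -> list:
    from .synthetic import SievingRecord

    df = pd.read_csv(path, dtype={"sample_id": str, "calendar_week": str})
    return [
        SievingRecord(
            sample_id=row.sample_id,
            calendar_week=row.calendar_week,
            csps_percent=float(row.csps_percent),
        )
        for row in df.itertuples()
    ]


def save_sieving_csv(records, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "calendar_week": r.calendar_week,
                "csps_percent": r.csps_percent,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
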