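#!/usr/bin/env python
"""Simulate the study's data universe.

Generates a Processor-Gap sweep of ground-truth kernel-fragment sequences
(PG 1-4 mm), three inconsistent annotator variants of a stover sequence, a
simulated detector run, and physically sieved CSPS records — everything the
later analysis stages consume.  Writes COCO JSON + CSV under results/data/.
"""

import argparse
import dataclasses
from pathlib import Path

from silageqc.core import AnnotationSet, Calibration
from silageqc.io import save_annotations, save_detections, save_meta_table, save_sieving_csv
from silageqc.synthetic import (
    AnnotatorProfile,
    DetectorProfile,
    HarvestSimConfig,
    StoverModel,
    corrupt_annotations,
    generate_harvest,
    simulate_detector,
    simulate_sieving,
)

ANNOTATORS = {
    "A1": AnnotatorProfile(miss_base=0.55, miss_size_slope=-0.02,
                           vertex_jitter_px=4.0, false_positive_rate=0.3, seed=11),
    "A2": AnnotatorProfile(miss_base=0.35, miss_size_slope=-0.015,
                           vertex_jitter_px=3.0, false_positive_rate=0.6,
                           merge_prob=0.3, seed=12),
    "A3": AnnotatorProfile(miss_base=0.10, miss_size_slope=-0.01,
                           vertex_jitter_px=2.0, false_positive_rate=0.8, seed=13),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-images", type=int, default=60)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cal = Calibration()

    # PG sweep, kernel fragments (calendar weeks alternate for correlation)
    parts = []
    for k, pg in enumerate((1.0, 2.0, 3.0, 4.0)):
        cfg = HarvestSimConfig(
            n_images=args.n_images, pg_mm=pg, tloc_mm=6.0,
            sequence_id=f"pg{int(pg)}", seed=args.seed + k,
            calendar_week="CW40" if k % 2 == 0 else "CW43",
        )
        parts.append(generate_harvest(cfg))
    sweep = AnnotationSet(
        source_id="gt",
        images={i: r for p in parts for i, r in p.images.items()},
        instances=[i for p in parts for i in p.instances],
    )
    save_annotations(sweep, args.out / "kernels_gt.json")
    save_meta_table(sweep, args.out / "kernels_meta.csv")

    # stover sequence with three annotator variants
    stover_gt = generate_harvest(
        HarvestSimConfig(
            n_images=20, pg_mm=2.0, tloc_mm=4.0, sequence_id="stover",
            stover_model=StoverModel(),
            count_model=dataclasses.replace(HarvestSimConfig().count_model, base_rate=0.0),
            seed=args.seed + 100,
        )
    )
    save_annotations(stover_gt, args.out / "stover_gt.json")
    save_meta_table(stover_gt, args.out / "stover_meta.csv")
    for name, prof in ANNOTATORS.items():
        variant = corrupt_annotations(
            stover_gt, dataclasses.replace(prof, seed=prof.seed + args.seed)
        )
        save_annotations(
            dataclasses.replace(variant, source_id=name),
            args.out / f"stover_{name}.json",
        )

    # detector run over the kernel sweep
    det = simulate_detector(sweep, DetectorProfile(seed=args.seed + 200))
    save_detections(det, args.out / "kernels_det.json")

    # physically sieved CSPS per image sample
    sieve = simulate_sieving(sweep, cal, noise_sd=2.0, seed=args.seed + 300)
    save_sieving_csv(sieve, args.out / "sieving.csv")

    print(f"kernel sweep: {len(sweep.images)} images, {len(sweep)} instances")
    print(f"stover gt: {len(stover_gt)} instances; annotators: {list(ANNOTATORS)}")
    print(f"detector: {len(det)} detections; sieving: {len(sieve)} samples")
    print(f"written under {args.out}")


if __name__ == "__main__":
    main()
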