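#!/usr/bin/env python
"""Dataset statistics and machine-setting trends.

Summarises the simulated kernel-fragment sweep per Processor Gap: images,
instances, instances per image, size and axis statistics; then checks the
expected monotone trends (smaller PG -> more and smaller fragments) with
Spearman statistics.  Writes results/stats_by_pg.csv and
results/trend_report.json.
"""

import argparse
import json
from pathlib import Path

from silageqc.io import load_annotations, load_meta_table
from silageqc.stats import summarize, trend_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    meta, cal = load_meta_table(args.data / "kernels_meta.csv")
    aset = load_annotations(args.data / "kernels_gt.json", cal, meta, source_id="gt")

    table = summarize(aset)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "stats_by_pg.csv", index=False)
    print(table.to_string(index=False))

    report = trend_report(table)
    (args.out / "trend_report.json").write_text(
        json.dumps({"along": report.along, "strata": report.strata,
                    "all_monotone": report.all_monotone}, indent=2, default=str)
    )
    verdict = "monotone" if report.all_monotone else "VIOLATED"
    print(f"\nPG trend (more+smaller fragments at narrow gap): {verdict}")
    for stratum, entry in report.strata.items():
        print(
            f"  TLOC {stratum}: spearman size {entry['spearman_size']:+.2f}, "
            f"count {entry['spearman_count']:+.2f}"
        )


if __name__ == "__main__":
    main()
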