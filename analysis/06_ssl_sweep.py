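#!/usr/bin/env python
"""Toy teacher-student hyper-parameter sweep.

Runs the confidence-threshold x unsupervised-images x unsupervised-weight
grid ({0.1, 0.3, 0.5, 0.7} x {1, 4} x {0.5, 4}) of the teacher-student
update rules on the two-cluster toy detector, against a supervised-only
baseline trained for the same number of iterations.  Writes
results/ssl_sweep.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from silageqc.ssl_rules import SSLConfig, ToyProblem, ssl_sweep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SSLConfig(seed=args.seed).scaled_down()
    rows = ssl_sweep(ToyProblem(), cfg)
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "ssl_sweep.csv", index=False)
    print(df.to_string(index=False))

    base = df.loc[df.run_id == "baseline", "teacher_error"].iloc[0]
    ok = df[(df.run_id != "baseline") & ~df.diverged]
    best = ok.loc[ok.teacher_error.idxmin()]
    print(
        f"\nbaseline held-out error {base:.4f}; best SSL run {best.run_id} "
        f"at {best.teacher_error:.4f} "
        f"({'improves' if best.teacher_error <= base else 'does not improve'})"
    )


if __name__ == "__main__":
    main()
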