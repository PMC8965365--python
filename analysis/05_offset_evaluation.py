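#!/usr/bin/env python
"""Pool the per-garden evaluations from the case runs and rank the metrics.

Reads the evaluation tables written by 04_multilocus_cases.py (and/or
03_single_locus.py), pools them, and writes the mean Spearman correlation of
every offset metric with common-garden fitness, split by range-core vs
range-edge gardens.

Usage: python analysis/05_offset_evaluation.py [--runs results/cases/case1 ...]
"""

import argparse
from pathlib import Path

import pandas as pd

from offsetlab.transplant import core_edge_summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument(
        "--runs",
        nargs="+",
        default=sorted(str(p) for p in Path("results/cases").glob("case*")),
    )
    ap.add_argument("--out", type=str, default="results/metric_ranking.tsv")
    args = ap.parse_args()
    if not args.runs:
        raise SystemExit("no run directories found; run 04_multilocus_cases.py first")

    frames = []
    for run_dir in args.runs:
        path = Path(run_dir) / "evaluation.tsv"
        if not path.exists():
            raise SystemExit(f"missing {path}")
        df = pd.read_csv(path, sep="\t")
        df.insert(0, "run", Path(run_dir).name)
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)

    # |rho|: a metric is useful whether it tracks fitness or its decline
    pooled["rho"] = pooled["rho"].abs()
    summary = core_edge_summary(pooled).sort_values("edge", ascending=False)
    summary.to_csv(args.out, sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
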