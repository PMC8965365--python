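#!/usr/bin/env python
"""Neutral deme-size scenarios: does drift masquerade as offset?

Runs the three deme-size schemes (equal, increasing, decreasing) at the frozen
desk scale, computes the adjacent-shift GF Offset per deme, and summarizes the
Pearson correlation between deme size and offset per replicate.

Usage: python analysis/02_drift_confounding.py [--seed 211] [--replicates 5]
"""

import argparse
from pathlib import Path

import pandas as pd

from offsetlab.pipeline import q1_run_config, run_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=211)
    ap.add_argument("--replicates", type=int, default=5)
    ap.add_argument("--out", type=str, default="results/drift")
    args = ap.parse_args()

    frames = []
    for scheme in ("equal", "increasing", "decreasing"):
        cfg = q1_run_config(
            scheme,
            master_seed=args.seed,
            replicates=args.replicates,
            out_dir=str(Path(args.out) / scheme),
        )
        manifest = run_all(cfg)
        summary = pd.read_csv(manifest.parent / "summary.tsv", sep="\t")
        summary.insert(0, "scheme", scheme)
        frames.append(summary)
        print(f"{scheme}: pearson_r = {summary['pearson_r'].round(3).tolist()}")
    pooled = pd.concat(frames, ignore_index=True)
    pooled.to_csv(Path(args.out) / "size_offset_correlations.tsv", sep="\t", index=False)
    print(f"wrote {args.out}/size_offset_correlations.tsv")


if __name__ == "__main__":
    main()
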