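#!/usr/bin/env python
"""Single-locus antagonistic pleiotropy along a linear gradient.

Runs the single-locus scenario at desk scale, fits turnover functions, computes
every offset metric, and evaluates them against common-garden fitness.

Usage: python analysis/03_single_locus.py [--seed 307] [--replicates 3]
"""

import argparse

import pandas as pd

from offsetlab.pipeline import run_all, transplant_run_config


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=307)
    ap.add_argument("--replicates", type=int, default=3)
    ap.add_argument("--out", type=str, default="results/single_locus")
    args = ap.parse_args()

    cfg = transplant_run_config(
        "single_locus",
        master_seed=args.seed,
        replicates=args.replicates,
        out_dir=args.out,
    )
    manifest = run_all(cfg)
    summary = pd.read_csv(manifest.parent / "summary.tsv", sep="\t")
    print(summary.to_string(index=False))
    print(f"wrote {manifest}")


if __name__ == "__main__":
    main()
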