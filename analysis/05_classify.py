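#!/usr/bin/env python
"""Stage 5: repeated 70/30 MLP classification of every endpoint and
feature set.

Reads cohort.csv, harmonized.csv, scores.csv and config.json; writes
runs.csv and report.csv.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from marrowpet.classify import run_experiment
from marrowpet.radiomics import SUV_FEATURES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = json.loads((args.outdir / "config.json").read_text())
    cohort = pd.read_csv(args.outdir / "cohort.csv")
    harmonized = pd.read_csv(args.outdir / "harmonized.csv")
    scores = pd.read_csv(args.outdir / "scores.csv").drop(columns=["patient_id"])
    report = run_experiment(
        cohort, harmonized[SUV_FEATURES], scores, master_seed=cfg["seed"]
    )
    report.frame().to_csv(args.outdir / "runs.csv", index=False)
    report.summary().to_csv(args.outdir / "report.csv", index=False)
    print(report.summary().to_string(index=False))


if __name__ == "__main__":
    main()
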