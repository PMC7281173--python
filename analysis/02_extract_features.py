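#!/usr/bin/env python
"""Stage 2: simulate each patient's PET volume, segment the pelvic MTV at
41% of SUVmax and extract the 19-feature record.

Reads cohort.csv + config.json from stage 1; writes features.csv.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from marrowpet.phantom import PhantomSpec
from marrowpet.pipeline import extract_cohort_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = json.loads((args.outdir / "config.json").read_text())
    table = pd.read_csv(args.outdir / "cohort.csv")
    pspec = (
        PhantomSpec.texture_only() if cfg["preset"] == "texture_only" else PhantomSpec()
    )
    feats = extract_cohort_features(table, pspec, master_seed=cfg["seed"])
    feats.to_csv(args.outdir / "features.csv", index=False)
    print(f"extracted {feats.shape[1] - 3} features for {len(feats)} patients")


if __name__ == "__main__":
    main()
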