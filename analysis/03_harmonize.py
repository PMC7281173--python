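#!/usr/bin/env python
"""Stage 3: ComBat-harmonize the feature table across scanners.

Reads features.csv; writes harmonized.csv and combat_model.json.
"""
import argparse
from pathlib import Path

import pandas as pd

from marrowpet.harmonization import combat_apply, combat_fit
from marrowpet.radiomics import ALL_FEATURES


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    feats = pd.read_csv(args.outdir / "features.csv")
    fmat = feats[ALL_FEATURES]
    model = combat_fit(fmat, feats["scanner_id"])
    model.to_json(args.outdir / "combat_model.json")
    harmonized = pd.concat(
        [feats[["patient_id", "scanner_id"]], combat_apply(fmat, feats["scanner_id"], model)],
        axis=1,
    )
    harmonized.to_csv(args.outdir / "harmonized.csv", index=False)
    print(f"harmonized {len(ALL_FEATURES)} features across "
          f"{feats['scanner_id'].nunique()} scanners")


if __name__ == "__main__":
    main()
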