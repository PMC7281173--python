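#!/usr/bin/env python
"""Stage 4: fit the correlation-matrix PCA signature (Kaiser retention).

Reads harmonized.csv; writes signature.json and scores.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from marrowpet.radiomics import ALL_FEATURES
from marrowpet.signature import apply_signature, fit_signature


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    harmonized = pd.read_csv(args.outdir / "harmonized.csv")
    sig = fit_signature(harmonized[ALL_FEATURES])
    sig.to_json(args.outdir / "signature.json")
    scores = apply_signature(harmonized[ALL_FEATURES], sig)
    pd.concat([harmonized[["patient_id"]], scores], axis=1).to_csv(
        args.outdir / "scores.csv", index=False
    )
    print(f"retained {sig.n_retained} components (eigenvalue > 1)")


if __name__ == "__main__":
    main()
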