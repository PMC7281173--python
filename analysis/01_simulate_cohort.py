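#!/usr/bin/env python
"""Stage 1: simulate the patient cohort table.

Writes cohort.csv, cohort_summary.csv and config.json (read by the later
stages) into the output directory.
"""
import argparse
import json
from pathlib import Path

from marrowpet.cohort import summarize_cohort
from marrowpet.phantom import CohortSpec, generate_cohort_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=97, help="cohort size")
    ap.add_argument(
        "--preset",
        choices=["default", "texture_only"],
        default="default",
        help="phantom preset used by stage 2",
    )
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = generate_cohort_table(CohortSpec(n_patients=args.n, seed=args.seed))
    table.to_csv(args.outdir / "cohort.csv", index=False)
    summarize_cohort(table).to_csv(args.outdir / "cohort_summary.csv", index=False)
    (args.outdir / "config.json").write_text(
        json.dumps({"seed": args.seed, "n_patients": args.n, "preset": args.preset}, indent=2)
    )
    print(f"wrote cohort of {len(table)} patients to {args.outdir}")


if __name__ == "__main__":
    main()
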