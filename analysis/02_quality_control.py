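#!/usr/bin/env python
"""Post-calling quality control.

Removes calls with total depth < 10 and re-calls every remaining genotype
from the alternative-allele depth ratio (DPRA: <0.3 -> 0/0, 0.3-0.7 ->
0/1, >0.7 -> 1/1). Reads results/cohort, writes the recalibrated variant
table and a QC action report under results/qc.
"""

import argparse
from pathlib import Path

from crsexome.io import read_bundle
from crsexome.qc import run_qc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--min-depth", type=int, default=10)
    args = ap.parse_args()

    bundle = read_bundle(args.results_dir / "cohort")
    variants, report = run_qc(bundle.variants, min_depth=args.min_depth)
    out = args.results_dir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    variants.to_csv(out / "variants_qc.tsv", sep="\t", index=False)
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)

    dropped = (report["action"] == "site_removed").sum()
    recalled = (report["action"] == "genotype_recalled").sum()
    print(f"{len(bundle.variants)} input calls -> {len(variants)} retained")
    print(f"{dropped} sites removed for low proband depth, "
          f"{recalled} genotypes re-called by DPRA")


if __name__ == "__main__":
    main()
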