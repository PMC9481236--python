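#!/usr/bin/env python
"""Per-patient diagnostic triage.

Converts ACMG pathogenicity classes into positive/negative genetic
diagnoses with inheritance-consistency rules (a lone heterozygous P/LP
allele in a recessive-only gene is negative; VUS never counts; P/LP CNVs
over catalog genes count). Writes results/triage.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from crsexome.io import build_bundle_catalog, read_bundle
from crsexome.triage import triage_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort_dir = args.results_dir / "cohort"
    bundle = read_bundle(cohort_dir)
    catalog = build_bundle_catalog(bundle, cohort_dir / "catalog")
    assigned = pd.read_csv(args.results_dir / "inheritance" / "assigned.tsv",
                           sep="\t", dtype={"chrom": str}).fillna(
                               {"partner": ""})
    outcomes, tallies = triage_cohort(bundle.patients, assigned,
                                      bundle.annotations, bundle.cnvs,
                                      catalog, bundle.gene_regions)

    out = args.results_dir / "triage"
    out.mkdir(parents=True, exist_ok=True)
    outcomes.to_csv(out / "outcomes.tsv", sep="\t", index=False)
    (out / "tallies.json").write_text(
        json.dumps(tallies, indent=1, sort_keys=True) + "\n")

    print(f"{tallies['panel_positive']} panel-diagnosed, "
          f"{tallies['wes_positive']} exome-diagnosed, "
          f"{tallies['both_negative']} negative by both, "
          f"{tallies['not_tested']} not exome-tested")
    wes_pos = outcomes[(outcomes["stage"] == "wes")
                       & (outcomes["status"] == "positive")]
    print("exome-stage diagnoses:",
          ", ".join(f"{r.patient_id}({r.causal_genes})"
                    for r in wes_pos.itertuples(index=False)))


if __name__ == "__main__":
    main()
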