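#!/usr/bin/env python
"""Two-part research pipeline for candidate-variant discovery.

Part one: deleteriousness (LoF, or DS >= 4 / CADD >= 20) plus
model-specific allele-frequency ceilings. Part two: top-20 prioritizer
rank under the same frequency ceilings. Variants found by both parts are
matched against the candidate-gene catalog and its OMIM models; benign
classes and review-excluded genes are flagged. Writes results/research.
"""

import argparse
from pathlib import Path

import pandas as pd

from crsexome.config import RunConfig
from crsexome.io import build_bundle_catalog, read_bundle
from crsexome.research import run_research_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = RunConfig()
    cohort_dir = args.results_dir / "cohort"
    bundle = read_bundle(cohort_dir)
    catalog = build_bundle_catalog(bundle, cohort_dir / "catalog")
    assigned = pd.read_csv(args.results_dir / "inheritance" / "assigned.tsv",
                           sep="\t", dtype={"chrom": str}).fillna(
                               {"partner": ""})
    candidates = run_research_pipeline(assigned, bundle.annotations, catalog,
                                       cfg.thresholds,
                                       cfg.review_excluded_genes)

    out = args.results_dir / "research"
    out.mkdir(parents=True, exist_ok=True)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)

    final = candidates[candidates["final"]]
    plp = final[final["acmg_class"].isin(["P", "LP"])]
    vus = final[final["acmg_class"] == "VUS"]
    print(f"{int(candidates['passed_part1'].sum())} variants pass part one, "
          f"{int(candidates['passed_part2'].sum())} pass part two, "
          f"{int(candidates['in_intersection'].sum())} in the intersection")
    print(f"final set: {len(final)} variants "
          f"({len(plp)} P/LP re-identified, {len(vus)} VUS candidates in "
          f"{vus['gene'].nunique()} genes / {vus['family'].nunique()} cases)")
    excluded = candidates[candidates["excluded_on_review"]
                          & candidates["in_intersection"]]
    print(f"{len(excluded)} intersection variants flagged at manual review "
          f"({excluded['review_reason'].value_counts().to_dict()})")


if __name__ == "__main__":
    main()
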