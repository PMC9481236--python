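#!/usr/bin/env python
"""Trio inheritance assignment and compound-heterozygote pairing.

Labels each carrier proband variant de novo / paternal / maternal /
biparental homozygote / hemizygous (carrier mother) / uncertain, with the
compatible genetic models; proband-only cases get assumed models.
Candidate compound-heterozygote pairs are the paternal x maternal
cross-product per gene. Writes results/inheritance.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from crsexome.inheritance import (annotate_partners, assign_inheritance_table,
                                  pair_compound_hets)
from crsexome.io import read_bundle


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = read_bundle(args.results_dir / "cohort")
    qc_variants = pd.read_csv(args.results_dir / "qc" / "variants_qc.tsv",
                              sep="\t", dtype={"chrom": str, "ref": str,
                                               "alt": str})
    assigned = assign_inheritance_table(qc_variants, bundle.patients)
    pairs = pair_compound_hets(assigned, bundle.annotations)
    assigned = annotate_partners(assigned, pairs)

    out = args.results_dir / "inheritance"
    out.mkdir(parents=True, exist_ok=True)
    assigned.to_csv(out / "assigned.tsv", sep="\t", index=False)
    (out / "comp_het_pairs.json").write_text(json.dumps(pairs, indent=1) + "\n")

    print(f"{len(assigned)} carrier variants assigned")
    print(assigned["mode"].value_counts().to_string())
    print(f"{len(pairs)} candidate compound-heterozygote pairs in "
          f"{assigned.loc[assigned['partner'] != '', 'family'].nunique()} "
          "families")


if __name__ == "__main__":
    main()
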