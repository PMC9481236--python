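"""Two-part research pipeline for candidate-variant discovery.

Part one keeps loss-of-function variants (frameshift, nonsense, splicing)
and deleterious missense / in-frame variants (deleterious score >= 4 or
CADD >= 20), then applies inheritance-model-specific allele-frequency
ceilings against two population databases (gnomAD and Huabiao). Part two
keeps the variants a phenotype-driven prioritizer ranked in the top 20 for
the proband, under the same frequency ceilings. Only variants identified by
both parts are retained; these are then required to hit the candidate-gene
catalog and to carry an inheritance model matching the gene's OMIM models.
Benign/likely-benign classifications and review-excluded genes are flagged
rather than silently dropped, mirroring the manual curation step.

Only SNVs and indels enter this pipeline; CNVs are handled by the
diagnostic triage alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import variant_key
from .catalog import GeneCatalog
from .config import FilterThresholds

LOF_CLASSES = frozenset({"frameshift", "nonsense", "splicing"})
SCORED_CLASSES = frozenset({"missense", "inframe_deletion", "inframe_insertion"})
BENIGN_CLASSES = frozenset({"synonymous", "intronic", "UTR", "upstream",
                            "downstream", "intergenic", "noncoding"})
KNOWN_CLASSES = LOF_CLASSES | SCORED_CLASSES | BENIGN_CLASSES
DOMINANT_MODELS = frozenset({"AD", "XLD"})


def functional_filter(variants: pd.DataFrame,
                      thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Retain LoF variants and deleterious missense / in-frame variants."""
    thresholds = thresholds or FilterThresholds()
    classes = set(variants["func_class"].dropna())
    unknown = classes - KNOWN_CLASSES
    if unknown:
        raise ValueError(f"unknown functional class token(s): {sorted(unknown)}")
    cadd = pd.to_numeric(variants["cadd"], errors="coerce")
    ds = pd.to_numeric(variants["ds"], errors="coerce")
    lof = variants["func_class"].isin(LOF_CLASSES)
    deleterious = variants["func_class"].isin(SCORED_CLASSES) & (
        (ds >= thresholds.ds_min) | (cadd >= thresholds.cadd_min))
    return variants[lof | deleterious].copy()


def _model_af_ceilings(model: str, t: FilterThresholds) -> tuple[float, float]:
    if model in DOMINANT_MODELS:
        return t.af_ad_gnomad, t.af_ad_huabiao
    return t.af_recessive_gnomad, t.af_recessive_huabiao


def frequency_filter(variants: pd.DataFrame,
                     thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Model-aware population-frequency filter.

    Each variant is evaluated under every inheritance model in its
    ``models`` column (``|``-separated); dominant-type models (AD, XLD) use
    the dominant ceilings, recessive-type models (AR, XLR) the recessive
    ones. A variant survives if it passes under any model; the surviving
    models are recorded in ``surviving_models``. Absent frequencies count
    as 0 (absent from the database).
    """
    thresholds = thresholds or FilterThresholds()
    gnomad = pd.to_numeric(variants["af_gnomad"], errors="coerce").fillna(0.0)
    huabiao = pd.to_numeric(variants["af_huabiao"], errors="coerce").fillna(0.0)
    for name, af in (("af_gnomad", gnomad), ("af_huabiao", huabiao)):
        if ((af < 0) | (af > 1)).any():
            raise ValueError(f"{name} outside [0, 1]")
    surviving = []
    for models, g, h in zip(variants["models"], gnomad, huabiao):
        ok = []
        for model in str(models).split("|"):
            g_max, h_max = _model_af_ceilings(model, thresholds)
            if g <= g_max and h <= h_max:
                ok.append(model)
        surviving.append("|".join(sorted(ok)))
    out = variants.copy()
    out["surviving_models"] = surviving
    return out[out["surviving_models"] != ""].copy()


def rank_filter(variants: pd.DataFrame, rank_max: int = 20) -> pd.DataFrame:
    """Keep variants the prioritizer ranked in the proband's top ``rank_max``.

    Variants without a rank are removed from part two (the prioritizer did
    not report them).
    """
    rank = pd.to_numeric(variants["exomiser_rank"], errors="coerce")
    return variants[rank <= rank_max].copy()


def intersect_parts(part1_keys: set[str], part2_keys: set[str]) -> set[str]:
    """Variants identified by both parts, on exact variant keys."""
    return set(part1_keys) & set(part2_keys)


def catalog_and_model_match(variants: pd.DataFrame, catalog: GeneCatalog,
                            ) -> pd.DataFrame:
    """Flag catalog membership and OMIM-model concordance.

    ``catalog_hit`` requires a (synonym-aware) catalog entry for the gene;
    ``omim_model_match`` requires a non-empty intersection between the
    variant's surviving models and the gene's OMIM models. Candidate
    compound-heterozygote pairs stand or fall as a unit: a member whose
    partner fails either check is dropped too.
    """
    out = variants.copy()
    hits, matches = [], []
    for row in out.itertuples(index=False):
        entry = catalog.lookup(row.gene)
        hits.append(entry is not None)
        models = set(str(row.surviving_models).split("|"))
        matches.append(entry is not None and bool(models & entry.omim_models))
    out["catalog_hit"] = hits
    out["omim_model_match"] = matches
    passed = out["catalog_hit"] & out["omim_model_match"]
    ok_keys = set(out.loc[passed, "key"])
    if "partner" in out.columns:
        unit_ok = [p == "" or pd.isna(p) or p in ok_keys for p in out["partner"]]
        passed = passed & pd.Series(unit_ok, index=out.index)
    out["model_stage_pass"] = passed
    return out


def run_research_pipeline(assigned: pd.DataFrame, annotations: pd.DataFrame,
                          catalog: GeneCatalog,
                          thresholds: FilterThresholds | None = None,
                          review_excluded_genes: tuple[str, ...] = ("APC",),
                          ) -> pd.DataFrame:
    """Run both parts over inheritance-assigned proband variants.

    ``assigned`` carries genotype / inheritance columns (including ``key``,
    ``models``, ``partner``); ``annotations`` the per-variant annotation
    table. Returns one row per annotated carrier variant with provenance
    flags: ``passed_part1``, ``passed_part2``, ``in_intersection``,
    ``catalog_hit``, ``omim_model_match``, ``excluded_on_review``,
    ``review_reason`` and ``final``.
    """
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    ann = annotations.copy()
    ann["key"] = [variant_key(r.family, r.chrom, r.pos, r.ref, r.alt)
                  for r in ann.itertuples(index=False)]
    ann = ann[ann["variant_kind"].isin(["SNV", "InDel"])]
    merged = ann.merge(
        assigned[["key", "mode", "models", "assumed", "partner", "proband_gt"]],
        on="key", how="inner")

    part1_func = functional_filter(merged, thresholds)
    part1 = frequency_filter(part1_func, thresholds)
    part1_keys = set(part1["key"])

    part2_af = frequency_filter(merged, thresholds)
    part2 = rank_filter(part2_af, thresholds.rank_max)
    part2_keys = set(part2["key"])

    both = intersect_parts(part1_keys, part2_keys)

    surviving = part1.set_index("key")["surviving_models"].to_dict()
    out = merged.copy()
    out["passed_part1"] = out["key"].isin(part1_keys)
    out["passed_part2"] = out["key"].isin(part2_keys)
    out["in_intersection"] = out["key"].isin(both)
    out["surviving_models"] = [surviving.get(k, "") for k in out["key"]]

    matched = catalog_and_model_match(out[out["in_intersection"]], catalog)
    pass_by_key = matched.set_index("key")
    out["catalog_hit"] = [bool(pass_by_key["catalog_hit"].get(k, False))
                          for k in out["key"]]
    out["omim_model_match"] = [bool(pass_by_key["omim_model_match"].get(k, False))
                               for k in out["key"]]
    model_pass = {k: bool(v) for k, v in pass_by_key["model_stage_pass"].items()}

    # manual-review stage: benign classifications and review-excluded genes
    review_set = {g.upper() for g in review_excluded_genes}
    reasons = []
    for row in out.itertuples(index=False):
        if row.acmg_class in ("LB", "B"):
            reasons.append("acmg_benign")
        elif str(row.gene).upper() in review_set:
            reasons.append("gene_review")
        else:
            reasons.append("")
    out["review_reason"] = reasons
    out["excluded_on_review"] = out["review_reason"] != ""

    out["final"] = [model_pass.get(k, False) and not excl
                    for k, excl in zip(out["key"], out["excluded_on_review"])]
    out = out.sort_values(["family", "chrom", "pos", "ref", "alt"],
                          kind="stable").reset_index(drop=True)
    return out
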