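"""Two-part research pipeline: filters, intersection, catalog matching."""

import numpy as np
import pandas as pd
import pytest

from crsexome.catalog import GeneCatalog
from crsexome.config import FilterThresholds
from crsexome.research import (catalog_and_model_match, frequency_filter,
                               functional_filter, intersect_parts,
                               rank_filter, run_research_pipeline)


def _ann(rows):
    cols = ["key", "func_class", "cadd", "ds", "af_gnomad", "af_huabiao",
            "exomiser_rank", "models", "gene"]
    return pd.DataFrame(rows, columns=cols)


@pytest.mark.parametrize("func,cadd,ds,kept", [
    ("missense", 20.7, 1, True),     # CADD alone suffices
    ("missense", 12.0, 4, True),     # DS alone suffices
    ("missense", 19.9, 3, False),    # below both thresholds
    ("missense", 20.0, 0, True),     # CADD boundary inclusive
    ("nonsense", None, None, True),  # LoF needs no scores
    ("frameshift", None, None, True),
    ("splicing", 5.0, 0, True),
    ("inframe_deletion", 22.1, 4, True),
    ("inframe_deletion", 10.0, 1, False),
    ("synonymous", 30.0, 8, False),  # class is never deleterious
    ("intronic", None, None, False),
])
def test_functional_filter(func, cadd, ds, kept):
    df = _ann([("k", func, cadd, ds, 0, 0, 1, "AD", "G")])
    assert (len(functional_filter(df)) == 1) is kept


def test_functional_filter_rejects_unknown_class():
    df = _ann([("k", "weird_class", 30, 5, 0, 0, 1, "AD", "G")])
    with pytest.raises(ValueError, match="weird_class"):
        functional_filter(df)


@pytest.mark.parametrize("models,af_g,af_h,kept,surviving", [
    ("AD", 4e-5, 1e-4, True, "AD"),
    ("AD", 5e-5, 5e-4, True, "AD"),      # ceilings are inclusive
    ("AD", 6e-5, 0.0, False, ""),
    ("AD", 0.0, 6e-4, False, ""),
    ("AR", 9e-4, 4e-3, True, "AR"),
    ("AR", 2e-3, 0.0, False, ""),
    ("XLR", 9e-4, 4e-3, True, "XLR"),
    ("AD|AR", 5e-4, 1e-3, True, "AR"),   # fails AD, survives AR
    ("AD|AR", 0.0, 0.0, True, "AD|AR"),  # absent from both databases
])
def test_frequency_filter_models(models, af_g, af_h, kept, surviving):
    df = _ann([("k", "missense", 25, 5, af_g, af_h, 1, models, "G")])
    out = frequency_filter(df)
    assert (len(out) == 1) is kept
    if kept:
        assert out.iloc[0]["surviving_models"] == surviving


def test_frequency_filter_rejects_invalid_frequency():
    df = _ann([("k", "missense", 25, 5, 1.5, 0, 1, "AD", "G")])
    with pytest.raises(ValueError, match="af_gnomad"):
        frequency_filter(df)


@pytest.mark.parametrize("rank,kept", [
    (17, True), (20, True), (21, False), (None, False), (1, True)])
def test_rank_filter_top20(rank, kept):
    df = _ann([("k", "missense", 25, 5, 0, 0, rank, "AD", "G")])
    assert (len(rank_filter(df, 20)) == 1) is kept


def test_intersection_is_exact_set_intersection():
    assert intersect_parts({"a", "b"}, {"b", "c"}) == {"b"}
    assert intersect_parts({"a"}, set()) == set()
    assert intersect_parts(set(), set()) == set()


def _catalog():
    cat = GeneCatalog()
    cat.add("SHROOM4", "hpo_skull", ["XLR"])
    cat.add("EVC", "literature", ["AR"])
    cat.add("ZNF462", "literature", ["AD"])
    return cat


def test_catalog_and_model_match_rules():
    df = _ann([
        ("k1", "missense", 33, 4, 0, 0, 18, "XLR", "SHROOM4"),
        ("k2", "missense", 25, 5, 0, 0, 1, "AD", "EVC"),      # model mismatch
        ("k3", "missense", 25, 5, 0, 0, 1, "AD", "NOT_A_GENE"),
    ])
    df["surviving_models"] = df["models"]
    out = catalog_and_model_match(df, _catalog())
    res = out.set_index("key")
    assert res.loc["k1", "model_stage_pass"]
    assert not res.loc["k2", "model_stage_pass"]
    assert res.loc["k2", "catalog_hit"] and not res.loc["k2", "omim_model_match"]
    assert not res.loc["k3", "catalog_hit"]


def test_comp_het_pairs_stand_or_fall_as_unit():
    df = _ann([
        ("k1", "missense", 25, 5, 0, 0, 1, "AR", "EVC"),
        ("k2", "missense", 25, 5, 0, 0, 1, "AR", "NOT_A_GENE"),
    ])
    df["surviving_models"] = df["models"]
    df["partner"] = ["k2", "k1"]
    out = catalog_and_model_match(df, _catalog())
    assert not out["model_stage_pass"].any()


def test_pipeline_recovers_all_spiked_plp_small_variants(analysis):
    final_keys = set(analysis.candidates.loc[analysis.candidates["final"], "key"])
    spiked = [m for m in analysis.bundle.manifest
              if m["expected_fate"] == "cmm_positive"
              and m["record_type"] == "small_variant"]
    assert len(spiked) == 7
    assert {m["key"] for m in spiked} <= final_keys


def test_pipeline_final_candidates_are_the_spiked_candidates(analysis):
    final = analysis.candidates[analysis.candidates["final"]]
    vus_final = set(final.loc[final["acmg_class"] == "VUS", "key"])
    expected = {m["key"] for m in analysis.bundle.manifest
                if m["expected_fate"] == "rp_candidate"}
    assert vus_final == expected
    assert len(expected) == 15


def test_review_exclusions_are_flagged_not_dropped(analysis):
    cand = analysis.candidates.set_index("key")
    apc = cand[cand["gene"] == "APC"]
    flagged = apc[apc["excluded_on_review"]]
    assert (flagged["review_reason"] == "gene_review").any()
    assert not flagged["final"].any()
    benign = cand[cand["review_reason"] == "acmg_benign"]
    assert set(benign["acmg_class"]) <= {"LB", "B"}


def test_final_set_membership_matches_brute_force_oracle(analysis):
    """Re-derive final membership for every spiked variant straight from the
    manifest payloads with an independent predicate evaluation."""
    t = FilterThresholds()
    catalog = analysis.catalog
    final_keys = set(analysis.candidates.loc[analysis.candidates["final"], "key"])
    pattern_models = {
        "de_novo": ["AD"], "proband_only": ["AD", "AR"],
        "maternal": ["AD", "AR"], "maternal_x": ["XLR"],
        "comp_het_paternal": ["AD", "AR"], "comp_het_maternal": ["AD", "AR"],
    }
    for m in analysis.bundle.manifest:
        if m["record_type"] != "small_variant":
            continue
        lof = m["func_class"] in ("frameshift", "nonsense", "splicing")
        scored = m["func_class"] in ("missense", "inframe_deletion",
                                     "inframe_insertion")
        cadd = m["cadd"] if m["cadd"] is not None else -np.inf
        ds = m["ds"] if m["ds"] is not None else -np.inf
        part1_func = lof or (scored and (ds >= t.ds_min or cadd >= t.cadd_min))
        models_ok = []
        for model in pattern_models[m["pattern"]]:
            if model in ("AD", "XLD"):
                ok = m["af_gnomad"] <= t.af_ad_gnomad and \
                    m["af_huabiao"] <= t.af_ad_huabiao
            else:
                ok = m["af_gnomad"] <= t.af_recessive_gnomad and \
                    m["af_huabiao"] <= t.af_recessive_huabiao
            if ok:
                models_ok.append(model)
        part2 = bool(models_ok) and m["exomiser_rank"] is not None \
            and m["exomiser_rank"] <= t.rank_max
        entry = catalog.lookup(m["gene"])
        cat_ok = entry is not None and bool(set(models_ok) & entry.omim_models)
        review_ok = m["acmg_class"] not in ("LB", "B") and m["gene"] != "APC"
        expected = part1_func and bool(models_ok) and part2 and cat_ok \
            and review_ok
        assert (m["key"] in final_keys) == expected, m["key"]


def test_tightening_thresholds_never_adds_variants(analysis, default_config):
    """Anti-monotonicity of the final set under stricter thresholds."""
    loose_final = set(analysis.candidates.loc[analysis.candidates["final"],
                                              "key"])
    tighter = [
        FilterThresholds(cadd_min=28.0, ds_min=6),
        FilterThresholds(rank_max=3),
        FilterThresholds(af_ad_gnomad=0.0, af_ad_huabiao=0.0,
                         af_recessive_gnomad=0.0, af_recessive_huabiao=0.0),
    ]
    for t in tighter:
        out = run_research_pipeline(
            analysis.assigned, analysis.bundle.annotations, analysis.catalog,
            t, default_config.review_excluded_genes)
        tight_final = set(out.loc[out["final"], "key"])
        assert tight_final <= loose_final, vars(t)


def test_provenance_flag_hierarchy(analysis):
    """final => intersection => both parts; intersection subsets each part."""
    c = analysis.candidates
    assert (c.loc[c["final"], "in_intersection"]).all()
    assert (c.loc[c["in_intersection"], "passed_part1"]).all()
    assert (c.loc[c["in_intersection"], "passed_part2"]).all()
    assert (c.loc[c["final"], "catalog_hit"]).all()
    assert (c.loc[c["final"], "omim_model_match"]).all()
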