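"""Synthetic cohort generator: counts, spikes, determinism, round-trips."""

import dataclasses

import pandas as pd
import pytest

from crsexome.cohort import CapacityError, CohortBundle, generate_cohort
from crsexome.config import CohortConfig, ConfigError
from crsexome.io import read_bundle, write_bundle


def test_default_cohort_reproduces_stage_counts(bundle):
    p = bundle.patients
    assert len(p) == 264
    assert (p["stage"] == "panel_positive").sum() == 139
    assert (p["stage"] == "wes").sum() == 102
    assert (p["stage"] == "lost").sum() == 23
    assert (p["group"] == "syndromic").sum() == 163
    assert (p["group"] == "non_syndromic").sum() == 101
    wes = p[p["stage"] == "wes"]
    assert (wes["design"] == "trio").sum() == 81
    assert (wes["design"] == "proband_only").sum() == 21
    assert (wes["sex"] == "M").sum() == 61
    assert (wes["group"] == "syndromic").sum() == 33


def test_cohort_sex_marginals(bundle):
    counts = bundle.patients.groupby(["group", "sex"]).size().to_dict()
    assert counts[("syndromic", "M")] == 87
    assert counts[("syndromic", "F")] == 76
    assert counts[("non_syndromic", "M")] == 58
    assert counts[("non_syndromic", "F")] == 43


def test_cohort_suture_marginals(bundle):
    counts = bundle.patients.groupby(["group", "suture"]).size().to_dict()
    assert counts[("syndromic", "Multiple")] == 54
    assert counts[("syndromic", "Uncertain")] == 31
    assert counts[("non_syndromic", "Sagittal")] == 41
    assert ("non_syndromic", "Uncertain") not in counts


def test_panel_allocation_distinct_variants(bundle):
    panel = bundle.patients[bundle.patients["stage"] == "panel_positive"]
    assert panel["panel_variant_id"].nunique() == 59
    assert panel["panel_gene"].nunique() == 9
    top = panel["panel_gene"].value_counts()
    assert top.idxmax() == "FGFR2"


def test_manifest_fate_counts(bundle):
    fates = pd.Series([m["expected_fate"] for m in bundle.manifest])
    assert (fates == "cmm_positive").sum() == 10  # 7 small + 3 CNV
    assert (fates == "rp_candidate").sum() == 15
    assert (fates == "potentially_pathogenic").sum() == 2
    kinds = pd.Series([m.get("variant_kind") for m in bundle.manifest
                       if m["expected_fate"] == "cmm_positive"])
    assert (kinds == "SNV").sum() == 4
    assert (kinds == "InDel").sum() == 3
    assert (kinds == "CNV").sum() == 3


def test_de_novo_spike_has_de_novo_genotypes(bundle):
    v = bundle.variants
    row = v[(v["family"] == "W033") & (v["chrom"] == "chr3")
            & (v["pos"] == 147131159)].iloc[0]
    assert row["proband_gt"] == "het"
    assert row["father_gt"] == "hom_ref"
    assert row["mother_gt"] == "hom_ref"


def test_uncertain_inheritance_withholds_parental_genotypes(bundle):
    v = bundle.variants
    row = v[(v["family"] == "W003") & (v["pos"] == 14716825)].iloc[0]
    assert row["proband_gt"] == "het"
    assert pd.isna(row["father_gt"]) and pd.isna(row["mother_gt"])
    design = bundle.patients.set_index("patient_id").loc["W003", "design"]
    assert design == "proband_only"


def test_comp_het_spikes_one_allele_per_parent(bundle):
    v = bundle.variants
    pair = v[(v["family"] == "W093") & (v["chrom"] == "chr9")
             & (v["pos"].isin([34658577, 34658598]))]
    assert len(pair) == 2
    origins = set()
    for _, row in pair.iterrows():
        if row["father_gt"] == "het":
            origins.add("paternal")
        if row["mother_gt"] == "het":
            origins.add("maternal")
    assert origins == {"paternal", "maternal"}


def test_cnv_spikes_are_three_deletions(bundle):
    spiked = bundle.cnvs[bundle.cnvs["gene"] == "TWIST1"]
    assert len(spiked) == 3
    assert (spiked["svtype"] == "DEL").all()
    assert (spiked["acmg_class"] == "P").all()


def test_decoys_never_collide_with_spikes(bundle):
    spiked = {(m["chrom"], m["pos"]) for m in bundle.manifest
              if m["record_type"] == "small_variant"}
    v = bundle.variants
    spike_keys = {m["key"] for m in bundle.manifest
                  if m["record_type"] == "small_variant"}
    decoys = v[~v.apply(lambda r: f"{r['family']}:{r['chrom']}:{r['pos']}:"
                        f"{r['ref']}:{r['alt']}" in spike_keys, axis=1)]
    decoy_sites = set(zip(decoys["chrom"], decoys["pos"]))
    assert not decoy_sites & spiked


def test_same_seed_is_bit_reproducible(small_cohort_config):
    a = generate_cohort(small_cohort_config)
    b = generate_cohort(small_cohort_config)
    assert a.manifest == b.manifest
    pd.testing.assert_frame_equal(a.variants, b.variants)
    pd.testing.assert_frame_equal(a.annotations, b.annotations)
    pd.testing.assert_frame_equal(a.patients, b.patients)


def test_different_seed_changes_decoys_not_spikes(small_cohort_config):
    a = generate_cohort(small_cohort_config)
    other = dataclasses.replace(small_cohort_config, seed=99)
    b = generate_cohort(other)
    assert a.manifest == b.manifest  # spike payloads are seed-independent
    assert not a.variants.equals(b.variants)


def test_empty_cohort_is_valid(tmp_path):
    cfg = CohortConfig(n_total=0, n_panel_pos=0, n_wes_enrolled=0, n_wes_pos=0,
                       n_lost=0, n_syndromic=0, n_nonsyndromic=0, n_trio=0,
                       n_proband_only=0, panel_pos_syndromic=0,
                       lost_syndromic=0, n_wes_male=0)
    bundle = generate_cohort(cfg)
    assert isinstance(bundle, CohortBundle)
    assert bundle.patients.empty and bundle.variants.empty
    assert bundle.manifest == []
    write_bundle(bundle, tmp_path / "empty")  # serializes without error


def test_inconsistent_config_names_violated_identity():
    with pytest.raises(ConfigError, match="n_panel_pos"):
        CohortConfig(n_panel_pos=100).validate()
    with pytest.raises(ConfigError, match="non-negative"):
        CohortConfig(n_lost=-1).validate()


def test_capacity_error_when_too_few_wes_patients():
    cfg = CohortConfig(n_total=60, n_panel_pos=5, n_wes_enrolled=50, n_lost=5,
                       n_syndromic=30, n_nonsyndromic=30, n_trio=40,
                       n_proband_only=10, panel_pos_syndromic=3,
                       lost_syndromic=2, n_wes_male=25, n_wes_pos=10)
    with pytest.raises(CapacityError):
        generate_cohort(cfg)


def test_bundle_round_trips_through_files(small_cohort_config, tmp_path):
    """Spike payloads survive VCF/TSV write + read unchanged."""
    bundle = generate_cohort(small_cohort_config)
    out = write_bundle(bundle, tmp_path / "cohort")
    back = read_bundle(out)
    assert back.manifest == bundle.manifest
    a = bundle.variants.reset_index(drop=True)
    b = back.variants.reset_index(drop=True)
    assert len(a) == len(b)
    for col in ("family", "chrom", "pos", "ref", "alt", "proband_gt",
                "father_gt", "mother_gt"):
        av = a[col].fillna("") if a[col].dtype == object else a[col]
        bv = b[col].fillna("") if b[col].dtype == object else b[col]
        assert (av == bv).all(), col
    assert (a["proband_dp"] == b["proband_dp"]).all()
    assert (a["proband_ad"] == b["proband_ad"]).all()
    assert len(back.annotations) == len(bundle.annotations)
    assert back.patients["patient_id"].tolist() == \
        bundle.patients["patient_id"].tolist()
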