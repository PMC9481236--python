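"""Trio inheritance assignment and compound-heterozygote pairing."""

from itertools import product

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crsexome.inheritance import (InheritanceCall, PedigreeError,
                                  annotate_partners, assign_inheritance,
                                  assign_inheritance_table,
                                  pair_compound_hets)

GTS = ("hom_ref", "het", "hom_alt")


def _autosomal_truth(pro, fa, mo):
    """Independent truth table for autosomal carrier probands."""
    carries = {"het": True, "hom_alt": True, "hom_ref": False}
    if pro == "het":
        if not carries[fa] and not carries[mo]:
            return "de_novo"
        if carries[fa] and not carries[mo]:
            return "paternal"
        if carries[mo] and not carries[fa]:
            return "maternal"
        return "uncertain"
    # hom_alt
    if carries[fa] and carries[mo]:
        return "hom_biparental"
    return "uncertain"


def test_autosomal_truth_table_exhaustive():
    """Every trio genotype combination matches the hand-written oracle."""
    for pro, fa, mo in product(("het", "hom_alt"), GTS, GTS):
        call = assign_inheritance(pro, fa, mo, "F", "chr2")
        assert call.mode == _autosomal_truth(pro, fa, mo), (pro, fa, mo)
        assert call.models, (pro, fa, mo)


def test_de_novo_models_are_dominant():
    call = assign_inheritance("het", "hom_ref", "hom_ref", "F", "chr3")
    assert call.mode == "de_novo"
    assert call.models == frozenset({"AD"})


def test_male_x_carrier_mother_is_hemizygous_maternal():
    call = assign_inheritance("hom_alt", "hom_ref", "het", "M", "chrX")
    assert call.mode == "hemizygous_maternal"
    assert call.models == frozenset({"XLR"})


def test_male_x_ignores_father_genotype():
    with_father = assign_inheritance("hom_alt", "hom_ref", "het", "M", "chrX")
    without = assign_inheritance("hom_alt", None, "het", "M", "chrX")
    assert with_father.mode == without.mode == "hemizygous_maternal"


def test_proband_only_is_assumed_uncertain():
    call = assign_inheritance("het", None, None, "M", "chr5")
    assert call.mode == "uncertain"
    assert call.assumed
    assert call.models == frozenset({"AD", "AR"})


def test_no_de_novo_with_missing_parent():
    """A missing parental genotype can never support a de novo call."""
    for fa, mo in [(None, "hom_ref"), ("hom_ref", None), ("missing", "hom_ref"),
                   (None, None), ("hom_ref", "missing")]:
        call = assign_inheritance("het", fa, mo, "F", "chr1")
        assert call.mode != "de_novo", (fa, mo)


def test_mendelian_inconsistency_kept_as_uncertain():
    call = assign_inheritance("hom_alt", "hom_ref", "hom_ref", "F", "chr8")
    assert call.mode == "uncertain"


def test_non_carrier_proband_rejected():
    with pytest.raises(ValueError, match="not carried"):
        assign_inheritance("hom_ref", "het", "het", "F", "chr1")
    with pytest.raises(ValueError, match="non-missing"):
        assign_inheritance("missing", "het", "het", "F", "chr1")


def test_empty_model_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        InheritanceCall("de_novo", frozenset())


def _frame(rows):
    cols = ["family", "chrom", "pos", "ref", "alt", "proband_gt",
            "father_gt", "mother_gt"]
    df = pd.DataFrame(rows, columns=cols)
    for role in ("proband", "father", "mother"):
        df[f"{role}_dp"] = 50
        df[f"{role}_ad"] = 25
    return df


def _patients(ids, sex="F"):
    return pd.DataFrame({"patient_id": list(ids), "sex": sex})


def test_table_assignment_requires_pedigree():
    df = _frame([("W999", "chr1", 100, "A", "T", "het", "hom_ref", "hom_ref")])
    with pytest.raises(PedigreeError):
        assign_inheritance_table(df, _patients(["W001"]))


@given(st.lists(st.sampled_from(["paternal", "maternal"]), min_size=0,
                max_size=8))
@settings(max_examples=100, deadline=None)
def test_comp_het_pairs_equal_cross_parent_enumeration(origins):
    """Pairing equals the exhaustive paternal x maternal cross-product."""
    rows, ann = [], []
    for i, origin in enumerate(origins):
        fa = "het" if origin == "paternal" else "hom_ref"
        mo = "het" if origin == "maternal" else "hom_ref"
        rows.append(("W001", "chr2", 1000 + i, "A", "T", "het", fa, mo))
        ann.append(("W001", "chr2", 1000 + i, "A", "T", "GENE1"))
    assigned = assign_inheritance_table(_frame(rows), _patients(["W001"]))
    pairs = pair_compound_hets(
        assigned, pd.DataFrame(ann, columns=["family", "chrom", "pos", "ref",
                                             "alt", "gene"]))
    pat = [f"W001:chr2:{1000+i}:A:T" for i, o in enumerate(origins)
           if o == "paternal"]
    mat = [f"W001:chr2:{1000+i}:A:T" for i, o in enumerate(origins)
           if o == "maternal"]
    expected = sorted((a, b) for a in pat for b in mat)
    assert pairs == expected


def test_two_paternal_one_maternal_gives_two_pairs():
    rows = [("W001", "chr2", 1000, "A", "T", "het", "het", "hom_ref"),
            ("W001", "chr2", 1001, "A", "T", "het", "het", "hom_ref"),
            ("W001", "chr2", 1002, "A", "T", "het", "hom_ref", "het")]
    ann = pd.DataFrame([("W001", "chr2", p, "A", "T", "G") for p in
                        (1000, 1001, 1002)],
                       columns=["family", "chrom", "pos", "ref", "alt", "gene"])
    assigned = assign_inheritance_table(_frame(rows), _patients(["W001"]))
    pairs = pair_compound_hets(assigned, ann)
    assert len(pairs) == 2


def test_same_parent_hets_never_pair():
    rows = [("W001", "chr2", 1000, "A", "T", "het", "hom_ref", "het"),
            ("W001", "chr2", 1001, "A", "T", "het", "hom_ref", "het")]
    ann = pd.DataFrame([("W001", "chr2", p, "A", "T", "G") for p in (1000, 1001)],
                       columns=["family", "chrom", "pos", "ref", "alt", "gene"])
    assigned = assign_inheritance_table(_frame(rows), _patients(["W001"]))
    assert pair_compound_hets(assigned, ann) == []


def test_fixture_comp_het_pairs_cross_parent(analysis):
    """The two spiked recessive pairs each have one allele per parent."""
    partnered = analysis.assigned[analysis.assigned["partner"] != ""]
    fams = set(partnered["family"])
    assert {"W093", "W095"} <= fams
    for fam in ("W093", "W095"):
        sub = partnered[partnered["family"] == fam]
        assert set(sub["mode"]) == {"paternal", "maternal"}


def test_annotate_partners_round_trip():
    pairs = [("k1", "k2")]
    df = pd.DataFrame({"key": ["k1", "k2", "k3"]})
    out = annotate_partners(df, pairs)
    assert list(out["partner"]) == ["k2", "k1", ""]
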