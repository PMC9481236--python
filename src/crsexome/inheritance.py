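"""Trio inheritance assignment and compound-heterozygote pairing.

Each proband variant receives an inheritance mode (de novo, paternal,
maternal, biparental homozygote, hemizygous with a carrier mother, or
uncertain) and the set of genetic models it is compatible with
(AD / AR / XLD / XLR). For the proband-only families the model is assumed:
the variant is carried forward under every model and tagged accordingly.
Phase is inferred from parental origin only; compound-heterozygote pairs
are the cross-product of paternally- and maternally-derived heterozygous
variants within a gene.

Mendelian-inconsistent configurations (e.g. a homozygote with a
reference-homozygous parent) are labelled uncertain rather than discarded:
DPRA recalibration can legitimately create them and they deserve review.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from ._util import is_x, variant_key

MODES = ("de_novo", "paternal", "maternal", "hom_biparental", "comp_het",
         "hemizygous_maternal", "uncertain")


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class InheritanceCall:
    mode: str
    models: frozenset[str]
    assumed: bool = False
    partner: str | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown inheritance mode {self.mode!r}")
        if not self.models:
            raise ValueError("model compatibility set may not be empty")


def _carries(gt: str | None) -> bool:
    return gt in ("het", "hom_alt")


def _missing(gt: str | None) -> bool:
    return gt is None or (isinstance(gt, float) and pd.isna(gt)) or gt == "missing"


def assign_inheritance(proband_gt: str, father_gt: str | None,
                       mother_gt: str | None, sex: str,
                       chromosome: str) -> InheritanceCall:
    """Assign the inheritance call for one proband variant.

    ``father_gt`` / ``mother_gt`` are ``None`` when the parent was not
    sequenced and ``"missing"`` for a no-call; both are treated as absent
    evidence. The proband genotype must be a carrier state.
    """
    if _missing(proband_gt):
        raise ValueError("proband genotype must be non-missing")
    if proband_gt == "hom_ref":
        raise ValueError("variant is not carried by the proband")
    x = is_x(chromosome)

    # Male X: hemizygous; only the mother transmits.
    if x and sex == "M":
        if _missing(mother_gt):
            return InheritanceCall("uncertain", frozenset({"XLD", "XLR"}),
                                   assumed=True)
        if _carries(mother_gt):
            return InheritanceCall("hemizygous_maternal", frozenset({"XLR"}))
        return InheritanceCall("de_novo", frozenset({"XLR", "XLD"}))

    if _missing(father_gt) or _missing(mother_gt):
        assumed_models = frozenset({"XLD", "XLR"}) if x else frozenset({"AD", "AR"})
        return InheritanceCall("uncertain", assumed_models, assumed=True)

    carrier_models = frozenset({"AD", "AR"} | ({"XLR"} if x else set()))
    if proband_gt == "het":
        pat, mat = _carries(father_gt), _carries(mother_gt)
        if not pat and not mat:
            return InheritanceCall("de_novo",
                                   frozenset({"XLD"}) if x else frozenset({"AD"}))
        if pat and not mat:
            return InheritanceCall("paternal", carrier_models)
        if mat and not pat:
            return InheritanceCall("maternal", carrier_models)
        return InheritanceCall("uncertain", carrier_models)  # ambiguous origin

    # proband hom_alt
    if _carries(father_gt) and _carries(mother_gt):
        return InheritanceCall("hom_biparental", frozenset({"AR"}))
    return InheritanceCall("uncertain", carrier_models)  # Mendelian inconsistency


def assign_inheritance_table(variants: pd.DataFrame,
                             patients: pd.DataFrame) -> pd.DataFrame:
    """Assign inheritance for every carrier proband variant in a wide table.

    Returns the carrier rows with ``mode``, ``models`` (``|``-joined),
    ``assumed`` and ``key`` columns appended. Probands homozygous-reference
    after recalibration are excluded (the variant is parental only).
    """
    sex_by_id = patients.set_index("patient_id")["sex"].to_dict()
    unknown = set(variants["family"]) - set(sex_by_id)
    if unknown:
        raise PedigreeError(f"families without pedigree entry: {sorted(unknown)[:5]}")
    carriers = variants[variants["proband_gt"].isin(["het", "hom_alt"])].copy()
    modes, models, assumed, keys = [], [], [], []
    fa = carriers["father_gt"] if "father_gt" in carriers else pd.Series(
        [None] * len(carriers), index=carriers.index)
    mo = carriers["mother_gt"] if "mother_gt" in carriers else pd.Series(
        [None] * len(carriers), index=carriers.index)
    for row, f_gt, m_gt in zip(carriers.itertuples(index=False), fa, mo):
        call = assign_inheritance(row.proband_gt, f_gt, m_gt,
                                  sex_by_id[row.family], row.chrom)
        modes.append(call.mode)
        models.append("|".join(sorted(call.models)))
        assumed.append(call.assumed)
        keys.append(variant_key(row.family, row.chrom, row.pos, row.ref, row.alt))
    carriers["key"] = keys
    carriers["mode"] = modes
    carriers["models"] = models
    carriers["assumed"] = assumed
    return carriers.reset_index(drop=True)


def pair_compound_hets(assigned: pd.DataFrame,
                       annotations: pd.DataFrame) -> list[tuple[str, str]]:
    """Enumerate candidate compound-heterozygote pairs per gene.

    A pair is one paternally-derived and one maternally-derived heterozygous
    variant of the same gene in the same proband; a variant may appear in
    several pairs. Returned as sorted ``(key, partner_key)`` tuples with the
    paternal member first.
    """
    ann = annotations.copy()
    ann["key"] = [variant_key(r.family, r.chrom, r.pos, r.ref, r.alt)
                  for r in ann.itertuples(index=False)]
    gene_by_key = ann.set_index("key")["gene"].to_dict()
    het = assigned[(assigned["proband_gt"] == "het")
                   & assigned["mode"].isin(["paternal", "maternal"])]
    pairs: list[tuple[str, str]] = []
    frame = het.assign(gene=[gene_by_key.get(k) for k in het["key"]])
    for (_, _gene), group in frame.groupby(["family", "gene"], sort=True):
        paternal = sorted(group.loc[group["mode"] == "paternal", "key"])
        maternal = sorted(group.loc[group["mode"] == "maternal", "key"])
        pairs.extend(product(paternal, maternal))
    return sorted(pairs)


def annotate_partners(assigned: pd.DataFrame,
                      pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Append a ``partner`` column (first partner by key order, or empty)."""
    partner: dict[str, str] = {}
    for a, b in pairs:
        partner.setdefault(a, b)
        partner.setdefault(b, a)
    out = assigned.copy()
    out["partner"] = [partner.get(k, "") for k in out["key"]]
    return out
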