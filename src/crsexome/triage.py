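"""Per-patient diagnostic triage from ACMG pathogenicity classes.

Classes arrive as annotations (the output of a clinical classification
pipeline is consumed, not re-implemented). A patient is positive iff they
carry:

* a P/LP small variant in a gene with a dominant or X-linked OMIM model
  compatible with the variant's inheritance call (an unresolved/assumed
  inheritance is compatible when its assumed model set intersects), or
* two P/LP alleles — a biparental homozygote or a compound-heterozygous
  pair — in a recessive-only gene, or
* a P/LP CNV overlapping a catalog gene.

A lone heterozygous P/LP allele in a recessive-only gene is explicitly
negative (``single_allele_ar_insufficient``); VUS never contributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import GeneCatalog

ACMG_CLASSES = frozenset({"P", "LP", "VUS", "LB", "B"})
DOMINANT_X_MODELS = frozenset({"AD", "XLD", "XLR"})


@dataclass
class DiagnosisOutcome:
    patient_id: str
    stage: str  # panel | wes | none
    status: str  # positive | negative
    causal_variants: list[str] = field(default_factory=list)
    causal_genes: list[str] = field(default_factory=list)
    rationale: str = "no_candidate"

    def __post_init__(self):
        if (self.status == "positive") != bool(self.causal_variants):
            raise ValueError("positive outcomes require causal variants "
                             "and vice versa")


def _check_classes(classes) -> None:
    bad = set(classes) - ACMG_CLASSES
    if bad:
        raise ValueError(f"unknown pathogenicity class token(s): {sorted(bad)}")


def _cnv_overlaps_gene(cnv, regions: pd.DataFrame) -> list[str]:
    """Genes whose 1-based half-open interval overlaps the CNV."""
    hits = []
    for r in regions.itertuples(index=False):
        if r.chrom == cnv.chrom and cnv.start < r.end and r.start < cnv.end:
            hits.append(r.gene)
    return hits


def triage_patient(patient_id: str, variants: pd.DataFrame,
                   cnvs: pd.DataFrame, catalog: GeneCatalog,
                   gene_regions: pd.DataFrame) -> DiagnosisOutcome:
    """Triage one exome-stage patient.

    ``variants`` are the patient's inheritance-assigned small variants
    (columns ``key``, ``gene``, ``acmg_class``, ``proband_gt``, ``mode``,
    ``models``, ``partner``); ``cnvs`` the patient's CNV calls.
    """
    _check_classes(variants["acmg_class"].dropna())
    if len(cnvs):
        _check_classes(cnvs["acmg_class"].dropna())

    causal: list[tuple[str, str]] = []
    saw_plp = False
    plp = variants[variants["acmg_class"].isin(["P", "LP"])]
    plp_keys = set(plp["key"])
    for row in plp.itertuples(index=False):
        saw_plp = True
        entry = catalog.lookup(row.gene)
        if entry is None:
            continue
        models = set(str(row.models).split("|"))
        compatible = models & entry.omim_models
        if compatible & DOMINANT_X_MODELS:
            causal.append((row.key, entry.symbol))
        elif "AR" in compatible:
            # recessive gene: need two alleles — homozygote or a P/LP partner
            partner = getattr(row, "partner", "")
            if row.mode == "hom_biparental" or (
                    isinstance(partner, str) and partner in plp_keys):
                causal.append((row.key, entry.symbol))

    cnv_causal: list[tuple[str, str]] = []
    for cnv in cnvs.itertuples(index=False):
        if cnv.acmg_class not in ("P", "LP"):
            continue
        saw_plp = True
        overlapped = _cnv_overlaps_gene(cnv, gene_regions)
        genes_in_catalog = [g for g in overlapped if catalog.lookup(g)]
        if genes_in_catalog:
            key = f"{patient_id}:{cnv.chrom}:{cnv.start}-{cnv.end}:{cnv.svtype}"
            cnv_causal.append((key, genes_in_catalog[0]))

    causal_all = causal + cnv_causal
    if causal_all:
        keys = [k for k, _ in causal_all]
        genes = sorted({g for _, g in causal_all})
        return DiagnosisOutcome(patient_id, "wes", "positive", keys, genes,
                                "plp_consistent")
    if saw_plp:
        return DiagnosisOutcome(patient_id, "wes", "negative",
                                rationale="single_allele_ar_insufficient")
    if (variants["acmg_class"] == "VUS").any():
        return DiagnosisOutcome(patient_id, "wes", "negative", rationale="vus_only")
    return DiagnosisOutcome(patient_id, "wes", "negative", rationale="no_candidate")


def triage_cohort(patients: pd.DataFrame, assigned: pd.DataFrame,
                  annotations: pd.DataFrame, cnvs: pd.DataFrame,
                  catalog: GeneCatalog, gene_regions: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, dict]:
    """Triage every patient; returns the outcome table and stage tallies.

    Panel-diagnosed patients keep their panel-stage positive outcome;
    exome-enrolled patients are triaged from their variant classes; lost
    patients were never tested past the panel.
    """
    from ._util import variant_key as _vk

    ann = annotations.copy()
    ann["key"] = [_vk(r.family, r.chrom, r.pos, r.ref, r.alt)
                  for r in ann.itertuples(index=False)]
    merged = assigned.merge(ann[["key", "gene", "acmg_class"]], on="key", how="left")

    rows = []
    for p in patients.itertuples(index=False):
        if p.stage == "panel_positive":
            rows.append(DiagnosisOutcome(
                p.patient_id, "panel", "positive", [p.panel_variant_id],
                [p.panel_gene], "plp_consistent"))
        elif p.stage == "lost":
            rows.append(DiagnosisOutcome(p.patient_id, "none", "negative",
                                         rationale="no_candidate"))
        else:
            pv = merged[merged["family"] == p.patient_id]
            pc = cnvs[cnvs["family"] == p.patient_id] if len(cnvs) else cnvs
            rows.append(triage_patient(p.patient_id, pv, pc, catalog, gene_regions))

    outcome = pd.DataFrame([{
        "patient_id": o.patient_id, "stage": o.stage, "status": o.status,
        "causal_variants": ";".join(o.causal_variants),
        "causal_genes": ";".join(o.causal_genes),
        "rationale": o.rationale,
    } for o in rows])
    tallies = {
        "panel_positive": int(((outcome["stage"] == "panel")
                               & (outcome["status"] == "positive")).sum()),
        "wes_positive": int(((outcome["stage"] == "wes")
                             & (outcome["status"] == "positive")).sum()),
        "both_negative": int(((outcome["stage"] == "wes")
                              & (outcome["status"] == "negative")).sum()),
        "not_tested": int((outcome["stage"] == "none").sum()),
    }
    tallies["total"] = len(outcome)
    return outcome, tallies
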