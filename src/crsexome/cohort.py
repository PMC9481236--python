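"""Synthetic trio-exome cohort generator.

Builds a fully self-contained fixture cohort whose stage-outcome counts
match the study conditions: 264 patients, 139 diagnosed by a 17-gene
panel, 102 panel-negative patients exome-sequenced (81 trios, 21
proband-only), 23 lost to follow-up. The known diagnostic and candidate
variant payloads (see :mod:`crsexome.truthset`) are spiked into their
designated exome-stage patients with genotype patterns consistent with
their stated inheritance; every other variant is a decoy drawn from
configurable frequency / deleteriousness distributions that exercise both
sides of every downstream filter.

Spike-in payloads are seed-independent; changing the seed changes decoys
only. Identical seeds give bit-identical bundles.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import truthset
from ._util import chrom_sort_key, variant_key
from .config import CohortConfig, ConfigError

SPIKE_DP = 100
SPIKE_AD = {"hom_ref": 1, "het": 48, "hom_alt": 98}

_PATTERN_GENOTYPES = {
    "de_novo": ("het", "hom_ref", "hom_ref"),
    "proband_only": ("het", None, None),
    "maternal": ("het", "hom_ref", "het"),
    "maternal_x": ("hom_alt", "hom_ref", "het"),
    "comp_het_paternal": ("het", "het", "hom_ref"),
    "comp_het_maternal": ("het", "hom_ref", "het"),
}

VARIANT_COLUMNS = ["family", "chrom", "pos", "ref", "alt",
                   "proband_gt", "proband_dp", "proband_ad",
                   "father_gt", "father_dp", "father_ad",
                   "mother_gt", "mother_dp", "mother_ad"]
ANNOTATION_COLUMNS = ["family", "chrom", "pos", "ref", "alt", "gene",
                      "transcript", "func_class", "cadd", "ds", "af_gnomad",
                      "af_huabiao", "exomiser_rank", "acmg_class", "variant_kind"]
CNV_COLUMNS = ["family", "chrom", "start", "end", "svtype", "gene",
               "acmg_class", "inheritance"]
PATIENT_COLUMNS = ["patient_id", "family_id", "sex", "group", "suture",
                   "stage", "design", "panel_gene", "panel_variant_id"]


_VARIANT_DTYPES = {"pos": "int64", "proband_dp": "float64",
                   "proband_ad": "float64", "father_dp": "float64",
                   "father_ad": "float64", "mother_dp": "float64",
                   "mother_ad": "float64"}
_ANNOTATION_DTYPES = {"pos": "int64", "cadd": "float64", "ds": "float64",
                      "af_gnomad": "float64", "af_huabiao": "float64",
                      "exomiser_rank": "float64"}


def _typed_frame(rows, columns, dtypes) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=columns)
    for col, dtype in dtypes.items():
        if len(df):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df[col] = df[col].astype(dtype)
    return df


def _concat(base: pd.DataFrame, new: pd.DataFrame) -> pd.DataFrame:
    if base.empty:
        return new.reset_index(drop=True)
    if new.empty:
        return base.reset_index(drop=True)
    return pd.concat([base, new], ignore_index=True)


class CapacityError(ConfigError):
    """Fewer exome-enrolled patients than required spike-in carriers."""


@dataclass
class CohortBundle:
    config: CohortConfig
    patients: pd.DataFrame
    pedigree: pd.DataFrame
    variants: pd.DataFrame
    annotations: pd.DataFrame
    cnvs: pd.DataFrame
    manifest: list[dict] = field(default_factory=list)
    gene_regions: pd.DataFrame = None
    catalog_sources: dict = field(default_factory=lambda: truthset.CATALOG_SOURCES)


def _largest_remainder(targets: dict, total: int) -> dict:
    """Scale an integer-valued quota dict to sum to ``total``."""
    base = sum(targets.values())
    if base == total or base == 0:
        return dict(targets)
    raw = {k: v * total / base for k, v in targets.items()}
    out = {k: int(v) for k, v in raw.items()}
    short = total - sum(out.values())
    order = sorted(targets, key=lambda k: (-(raw[k] - out[k]), k))
    for k in order[:short]:
        out[k] += 1
    return out


def _forced_attributes() -> dict[str, dict]:
    forced: dict[str, dict] = {}
    for v in truthset.all_spiked_small_variants():
        design = "proband_only" if v["pattern"] == "proband_only" else "trio"
        forced.setdefault(v["patient"], {}).update(
            sex=v["sex"], group=v["group"], suture=v["suture"], design=design)
    for c in truthset.DIAGNOSTIC_CNVS:
        entry = forced.setdefault(c["patient"], {})
        entry.update(sex=c["sex"], group=c["group"], suture=c["suture"])
        # a CNV labelled 'uncertain' has no parental evidence: proband-only
        entry.setdefault("design",
                         "proband_only" if c["inheritance"] == "uncertain" else "trio")
    return forced


def _build_patients(cfg: CohortConfig, spiking: bool) -> pd.DataFrame:
    wes_ids = [f"W{i:03d}" for i in range(1, cfg.n_wes_enrolled + 1)]
    panel_ids = [f"P{i:03d}" for i in range(1, cfg.n_panel_pos + 1)]
    lost_ids = [f"X{i:03d}" for i in range(1, cfg.n_lost + 1)]
    forced = _forced_attributes() if spiking else {}
    missing = sorted(set(forced) - set(wes_ids))
    if missing:
        raise CapacityError(
            f"{len(missing)} spike-in carrier(s) exceed the {cfg.n_wes_enrolled} "
            f"exome-enrolled patients (first missing: {missing[0]})")

    # exome-stage design: forced proband-only cases first, then fill in order
    forced_po = [p for p in wes_ids if forced.get(p, {}).get("design") == "proband_only"]
    forced_trio = [p for p in wes_ids if forced.get(p, {}).get("design") == "trio"]
    if len(forced_po) > cfg.n_proband_only:
        raise CapacityError("n_proband_only too small for the spiked "
                            "proband-only cases")
    if len(forced_trio) > cfg.n_trio:
        raise CapacityError("n_trio too small for the spiked trio cases")
    proband_only = set(forced_po)
    for pid in wes_ids:
        if len(proband_only) >= cfg.n_proband_only:
            break
        if pid not in forced:
            proband_only.add(pid)
    design = {p: ("proband_only" if p in proband_only else "trio") for p in wes_ids}

    # syndromic / non-syndromic per stage
    group: dict[str, str] = {p: forced[p]["group"] for p in forced}
    n_syn_left = cfg.n_wes_syndromic - sum(
        1 for p in forced if forced[p]["group"] == "syndromic")
    if n_syn_left < 0:
        raise ConfigError("syndromic exome-stage quota below the spiked count")
    for pid in wes_ids:
        if pid in group:
            continue
        group[pid] = "syndromic" if n_syn_left > 0 else "non_syndromic"
        n_syn_left -= 1 if group[pid] == "syndromic" else 0
    for i, pid in enumerate(panel_ids):
        group[pid] = "syndromic" if i < cfg.panel_pos_syndromic else "non_syndromic"
    for i, pid in enumerate(lost_ids):
        group[pid] = "syndromic" if i < cfg.lost_syndromic else "non_syndromic"

    # sexes: exome-stage male count is fixed; cohort-wide per-group sex
    # marginals are met with the remaining panel / lost patients
    n_group = {g: sum(1 for p in group.values() if p == g)
               for g in ("syndromic", "non_syndromic")}
    male_target = {}
    for g in ("syndromic", "non_syndromic"):
        m, f = truthset.SEX_MARGINALS[g]
        scaled = _largest_remainder({"M": m, "F": f}, n_group[g])
        male_target[g] = scaled["M"]
    sex: dict[str, str] = {p: forced[p]["sex"] for p in forced}
    males = {g: sum(1 for p, s in sex.items() if s == "M" and group[p] == g)
             for g in ("syndromic", "non_syndromic")}
    wes_males = sum(1 for p in wes_ids if sex.get(p) == "M")
    for pid in wes_ids:
        if pid in sex:
            continue
        g = group[pid]
        if wes_males < cfg.n_wes_male and males[g] < male_target[g]:
            sex[pid] = "M"
            wes_males += 1
            males[g] += 1
        else:
            sex[pid] = "F"
    for pid in panel_ids + lost_ids:
        g = group[pid]
        if males[g] < male_target[g]:
            sex[pid] = "M"
            males[g] += 1
        else:
            sex[pid] = "F"

    # suture-fusion types per group, honouring the cohort marginals
    suture: dict[str, str] = {p: forced[p]["suture"] for p in forced}
    for g in ("syndromic", "non_syndromic"):
        members = [p for p in panel_ids + wes_ids + lost_ids if group[p] == g]
        quota = _largest_remainder(truthset.SUTURE_MARGINALS[g], len(members))
        for p in members:
            if p in suture:
                if quota.get(suture[p], 0) > 0:
                    quota[suture[p]] -= 1
        order = [t for t in truthset.SUTURE_TYPES for _ in range(quota.get(t, 0))]
        it = iter(order)
        for p in members:
            if p not in suture:
                suture[p] = next(it, "Uncertain")

    # panel-stage diagnoses: gene and distinct-variant allocation
    panel_assign = []
    for gene, n_pat, n_var in truthset.PANEL_ALLOCATION:
        for j in range(n_pat):
            panel_assign.append((gene, f"{gene}.v{(j % n_var) + 1:02d}"))
    rows = []
    for i, pid in enumerate(panel_ids):
        gene, vid = panel_assign[i % len(panel_assign)] if panel_assign else ("", "")
        rows.append((pid, "", sex[pid], group[pid], suture[pid],
                     "panel_positive", "", gene, vid))
    for pid in wes_ids:
        rows.append((pid, f"F{pid}", sex[pid], group[pid], suture[pid],
                     "wes", design[pid], "", ""))
    for pid in lost_ids:
        rows.append((pid, "", sex[pid], group[pid], suture[pid],
                     "lost", "", "", ""))
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def _build_pedigree(patients: pd.DataFrame) -> pd.DataFrame:
    rows = []
    wes = patients[patients["stage"] == "wes"]
    for p in wes.itertuples(index=False):
        sex_code = 1 if p.sex == "M" else 2
        if p.design == "trio":
            rows.append((p.family_id, f"{p.patient_id}_fa", "0", "0", 1, 1))
            rows.append((p.family_id, f"{p.patient_id}_mo", "0", "0", 2, 1))
            rows.append((p.family_id, p.patient_id, f"{p.patient_id}_fa",
                         f"{p.patient_id}_mo", sex_code, 2))
        else:
            rows.append((p.family_id, p.patient_id, "0", "0", sex_code, 2))
    return pd.DataFrame(rows, columns=["family", "individual", "father",
                                       "mother", "sex", "phenotype"])


def _spike_row(v: dict, design: str) -> tuple[dict, dict]:
    """Variant-table row and annotation row for one small-variant spike."""
    pattern = v["pattern"]
    if design == "proband_only" and pattern != "proband_only":
        raise ConfigError(f"{v['patient']}: trio pattern {pattern} in a "
                          "proband-only family")
    pro, fa, mo = _PATTERN_GENOTYPES[pattern]
    row = dict(family=v["patient"], chrom=v["chrom"], pos=v["pos"],
               ref=v["ref"], alt=v["alt"],
               proband_gt=pro, proband_dp=SPIKE_DP, proband_ad=SPIKE_AD[pro])
    for role, gt in (("father", fa), ("mother", mo)):
        row[f"{role}_gt"] = gt
        row[f"{role}_dp"] = SPIKE_DP if gt else None
        row[f"{role}_ad"] = SPIKE_AD[gt] if gt else None
    ann = dict(family=v["patient"], chrom=v["chrom"], pos=v["pos"],
               ref=v["ref"], alt=v["alt"], gene=v["gene"],
               transcript=v["transcript"], func_class=v["func_class"],
               cadd=v["cadd"], ds=v["ds"], af_gnomad=0.0, af_huabiao=0.0,
               exomiser_rank=v["rank"], acmg_class=v["acmg"],
               variant_kind=v["kind"])
    return row, ann


def _manifest_entry(v: dict, fate: str) -> dict:
    pro, fa, mo = _PATTERN_GENOTYPES[v["pattern"]]
    return dict(patient=v["patient"], record_type="small_variant",
                key=variant_key(v["patient"], v["chrom"], v["pos"],
                                v["ref"], v["alt"]),
                chrom=v["chrom"], pos=v["pos"], ref=v["ref"], alt=v["alt"],
                gene=v["gene"], transcript=v["transcript"],
                func_class=v["func_class"], cadd=v["cadd"], ds=v["ds"],
                exomiser_rank=v["rank"], af_gnomad=0.0, af_huabiao=0.0,
                acmg_class=v["acmg"], variant_kind=v["kind"],
                pattern=v["pattern"],
                genotypes=dict(proband=pro, father=fa, mother=mo),
                expected_fate=fate)


def _spike_small_variants(bundle: CohortBundle, payloads, fate: str) -> CohortBundle:
    design = bundle.patients.set_index("patient_id")["design"].to_dict()
    missing = sorted({v["patient"] for v in payloads} - set(design))
    if missing:
        raise CapacityError(f"spike-in carriers missing from the cohort: {missing}")
    var_rows, ann_rows, manifest = [], [], []
    for v in payloads:
        row, ann = _spike_row(v, design[v["patient"]])
        var_rows.append(row)
        ann_rows.append(ann)
        manifest.append(_manifest_entry(v, fate))
    out = copy.copy(bundle)
    out.variants = _concat(bundle.variants, _typed_frame(
        var_rows, VARIANT_COLUMNS, _VARIANT_DTYPES))
    out.annotations = _concat(bundle.annotations, _typed_frame(
        ann_rows, ANNOTATION_COLUMNS, _ANNOTATION_DTYPES))
    out.manifest = bundle.manifest + manifest
    return out


def spike_diagnostic_variants(bundle: CohortBundle) -> CohortBundle:
    """Place the ten diagnostic P/LP payloads (4 SNVs, 3 indels, 3 CNVs)."""
    n_wes = int((bundle.patients["stage"] == "wes").sum())
    needed = len({v["patient"] for v in truthset.DIAGNOSTIC_SMALL_VARIANTS}
                 | {c["patient"] for c in truthset.DIAGNOSTIC_CNVS})
    if n_wes < needed:
        raise CapacityError(f"{needed} diagnostic spike-in carriers but only "
                            f"{n_wes} exome-enrolled patients")
    out = _spike_small_variants(
        bundle, truthset.DIAGNOSTIC_SMALL_VARIANTS, "cmm_positive")
    cnv_rows, manifest = [], []
    for c in truthset.DIAGNOSTIC_CNVS:
        cnv_rows.append(dict(family=c["patient"], chrom=c["chrom"],
                             start=c["start"], end=c["end"], svtype=c["svtype"],
                             gene=c["gene"], acmg_class=c["acmg"],
                             inheritance=c["inheritance"]))
        manifest.append(dict(patient=c["patient"], record_type="cnv",
                             key=f"{c['patient']}:{c['chrom']}:"
                                 f"{c['start']}-{c['end']}:{c['svtype']}",
                             chrom=c["chrom"], start=c["start"], end=c["end"],
                             svtype=c["svtype"], gene=c["gene"],
                             acmg_class=c["acmg"], inheritance=c["inheritance"],
                             variant_kind="CNV", expected_fate="cmm_positive"))
    out.cnvs = _concat(out.cnvs, pd.DataFrame(cnv_rows, columns=CNV_COLUMNS))
    out.manifest = out.manifest + manifest
    return out


def spike_candidate_variants(bundle: CohortBundle) -> CohortBundle:
    """Place the fifteen research-pipeline candidate payloads.

    Eleven single-variant cases plus two compound-heterozygous pairs, each
    with one paternal and one maternal allele.
    """
    carriers = {v["patient"] for v in truthset.CANDIDATE_VARIANTS}
    diagnostic = {v["patient"] for v in truthset.DIAGNOSTIC_SMALL_VARIANTS} | {
        c["patient"] for c in truthset.DIAGNOSTIC_CNVS}
    assert not carriers & diagnostic
    n_wes = int((bundle.patients["stage"] == "wes").sum())
    if n_wes < len(carriers | diagnostic):
        raise CapacityError("not enough exome-enrolled patients distinct from "
                            "the diagnostic carriers")
    return _spike_small_variants(bundle, truthset.CANDIDATE_VARIANTS, "rp_candidate")


def spike_ancillary_variants(bundle: CohortBundle) -> CohortBundle:
    """Place the potentially-pathogenic cases and the review-excluded decoy."""
    out = _spike_small_variants(
        bundle, truthset.POTENTIALLY_PATHOGENIC_VARIANTS, "potentially_pathogenic")
    return _spike_small_variants(
        out, truthset.REVIEW_EXCLUDED_VARIANTS, "decoy")


_DECOY_CLASSES = np.array(["synonymous", "intronic", "missense", "UTR",
                           "splicing", "frameshift", "nonsense",
                           "inframe_deletion"])
_DECOY_CLASS_P = np.array([0.33, 0.25, 0.30, 0.05, 0.02, 0.02, 0.02, 0.01])
_BASES = np.array(list("ACGT"))


def _decoy_variant(rng: np.random.Generator, cfg: CohortConfig, pid: str,
                   design: str, catalog_genes: list[str],
                   used: set) -> tuple[dict, dict]:
    while True:
        chrom = "chrX" if rng.random() < 0.05 else f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1_000_000, 200_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            break
    if rng.random() < 0.85:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        ref, alt, kind = str(ref), str(alt), "SNV"
    else:
        anchor = str(rng.choice(_BASES))
        tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        ref, alt = (anchor + tail, anchor) if rng.random() < 0.5 else \
            (anchor, anchor + tail)
        kind = "InDel"
    func_class = str(rng.choice(_DECOY_CLASSES, p=_DECOY_CLASS_P))
    in_catalog = rng.random() < 0.12
    gene = str(rng.choice(catalog_genes)) if in_catalog \
        else f"DG{rng.integers(1, 400):03d}"
    cadd = round(float(max(0.0, rng.normal(25, 5) if rng.random() < 0.3
                           else rng.normal(8, 4))), 1)
    ds = int(rng.integers(4, 9)) if rng.random() < 0.15 \
        else int(min(10, rng.poisson(1.5)))
    if rng.random() < 0.10:
        af_g = 0.0
    else:
        af_g = float(10 ** rng.uniform(cfg.decoy_af_log10_min,
                                       cfg.decoy_af_log10_max))
    af_h = 0.0 if af_g == 0.0 else float(
        min(0.5, af_g * 10 ** rng.normal(0.0, 0.5)))
    rank = int(rng.integers(1, 251)) if rng.random() < 0.3 else None
    if in_catalog:
        acmg = "LB" if rng.random() < 0.5 else "B"
    else:
        acmg = str(rng.choice(["VUS", "LB", "B"], p=[0.2, 0.4, 0.4]))

    # genotypes
    def sample_depths(gt):
        if rng.random() < cfg.decoy_low_depth_rate:
            dp = int(rng.integers(0, 10))
        else:
            dp = int(max(1, rng.poisson(100)))
        if rng.random() < 0.03:  # noisy allele balance; exercises recalibration
            ad = int(rng.integers(0, dp + 1))
        else:
            p = {"hom_ref": 0.02, "het": 0.5, "hom_alt": 0.97}[gt]
            ad = int(rng.binomial(dp, p))
        return dp, ad

    if design == "trio":
        p_car = float(np.clip(af_g * 20, 0.01, 0.4))
        parent_gts = []
        for _ in range(2):
            u = rng.random()
            parent_gts.append("hom_alt" if u < p_car * 0.05
                              else "het" if u < p_car else "hom_ref")
        alleles = 0
        for g in parent_gts:
            alleles += 1 if g == "hom_alt" else int(rng.random() < 0.5) \
                if g == "het" else 0
        if alleles == 0 and rng.random() < 0.3:
            alleles = 1  # apparent de novo decoy
        pro_gt = ["hom_ref", "het", "hom_alt"][alleles]
        fa_gt, mo_gt = parent_gts
    else:
        pro_gt = "het" if rng.random() < 0.92 else "hom_alt"
        fa_gt = mo_gt = None
    row = dict(family=pid, chrom=chrom, pos=pos, ref=ref, alt=alt)
    dp, ad = sample_depths(pro_gt)
    row.update(proband_gt=pro_gt, proband_dp=dp, proband_ad=ad)
    for role, gt in (("father", fa_gt), ("mother", mo_gt)):
        if gt is None:
            row.update({f"{role}_gt": None, f"{role}_dp": None, f"{role}_ad": None})
        else:
            dp, ad = sample_depths(gt)
            row.update({f"{role}_gt": gt, f"{role}_dp": dp, f"{role}_ad": ad})
    ann = dict(family=pid, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
               transcript=f"NM_{rng.integers(100000, 999999)}",
               func_class=func_class, cadd=cadd, ds=ds, af_gnomad=af_g,
               af_huabiao=af_h, exomiser_rank=rank, acmg_class=acmg,
               variant_kind=kind)
    return row, ann


def add_decoys(bundle: CohortBundle, rng: np.random.Generator) -> CohortBundle:
    """Append decoy small variants and CNVs; never collides with spikes."""
    cfg = bundle.config
    used = {(r.chrom, r.pos) for r in bundle.variants.itertuples(index=False)}
    catalog_genes = sorted({sym for entries in truthset.CATALOG_SOURCES.values()
                            for sym, _, _ in entries})
    wes = bundle.patients[bundle.patients["stage"] == "wes"]
    var_rows, ann_rows = [], []
    for p in wes.itertuples(index=False):
        for _ in range(cfg.decoy_variants_per_proband):
            row, ann = _decoy_variant(rng, cfg, p.patient_id, p.design,
                                      catalog_genes, used)
            var_rows.append(row)
            ann_rows.append(ann)
    cnv_rows = []
    n_cnv_decoys = min(6, len(wes))
    if n_cnv_decoys:
        fams = rng.choice(wes["patient_id"].to_numpy(), size=n_cnv_decoys,
                          replace=False)
        for fam in fams:
            chrom = f"chr{rng.integers(1, 23)}"
            start = int(rng.integers(1_000_000, 100_000_000))
            end = start + int(rng.integers(50_000, 2_000_000))
            cnv_rows.append(dict(
                family=str(fam), chrom=chrom, start=start, end=end,
                svtype=str(rng.choice(["DEL", "DUP"])), gene=f"DG{rng.integers(1, 400):03d}",
                acmg_class=str(rng.choice(["VUS", "LB", "B"])),
                inheritance="uncertain"))
    out = copy.copy(bundle)
    out.variants = _concat(bundle.variants, _typed_frame(
        var_rows, VARIANT_COLUMNS, _VARIANT_DTYPES))
    out.annotations = _concat(bundle.annotations, _typed_frame(
        ann_rows, ANNOTATION_COLUMNS, _ANNOTATION_DTYPES))
    if cnv_rows:
        out.cnvs = _concat(bundle.cnvs, pd.DataFrame(cnv_rows,
                                                     columns=CNV_COLUMNS))
    return out


def _sort_bundle(bundle: CohortBundle) -> CohortBundle:
    v = bundle.variants
    v = v.assign(_c=[chrom_sort_key(c) for c in v["chrom"]]).sort_values(
        ["family", "_c", "pos", "ref", "alt"], kind="stable").drop(columns="_c")
    a = bundle.annotations
    a = a.assign(_c=[chrom_sort_key(c) for c in a["chrom"]]).sort_values(
        ["family", "_c", "pos", "ref", "alt"], kind="stable").drop(columns="_c")
    out = copy.copy(bundle)
    out.variants = v.reset_index(drop=True)
    out.annotations = a.reset_index(drop=True)
    out.cnvs = bundle.cnvs.sort_values(
        ["family", "chrom", "start", "end"], kind="stable").reset_index(drop=True)
    out.manifest = sorted(bundle.manifest,
                          key=lambda m: (m["patient"], m["record_type"], m["key"]))
    return out


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate the full synthetic cohort bundle."""
    cfg = config or CohortConfig()
    cfg.validate()
    spiking = cfg.n_wes_enrolled > 0
    rng = np.random.default_rng(cfg.seed)
    patients = _build_patients(cfg, spiking)
    bundle = CohortBundle(
        config=cfg,
        patients=patients,
        pedigree=_build_pedigree(patients),
        variants=_typed_frame([], VARIANT_COLUMNS, _VARIANT_DTYPES),
        annotations=_typed_frame([], ANNOTATION_COLUMNS, _ANNOTATION_DTYPES),
        cnvs=pd.DataFrame(columns=CNV_COLUMNS),
        gene_regions=pd.DataFrame(truthset.GENE_REGIONS,
                                  columns=["gene", "chrom", "start", "end"]),
    )
    if spiking:
        bundle = spike_diagnostic_variants(bundle)
        bundle = spike_candidate_variants(bundle)
        bundle = spike_ancillary_variants(bundle)
    bundle = add_decoys(bundle, rng)
    return _sort_bundle(bundle)
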