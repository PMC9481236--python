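"""Ground-truth payloads spiked into the synthetic cohort.

These constants are the study conditions the generator reproduces: the ten
diagnostic pathogenic/likely-pathogenic findings of the exome stage (four
SNVs, three indels, three CNV deletions), the fifteen research-pipeline
candidate variants (including two compound-heterozygous pairs), the
"potentially pathogenic" cases that the triage rules must leave negative,
and the candidate-gene catalog sources. Coordinates (GRCh37), functional
classes, CADD / deleterious scores, prioritizer ranks, inheritance labels
and ACMG classes are taken from the published cohort findings; REF/ALT
anchor bases for the indels are synthetic (plausible stand-ins, since only
HGVS-style coordinate ranges are published). Population allele frequencies
of the spiked variants are 0 — they are novel or absent from both gnomAD
and Huabiao.

Spike fate labels:
  cmm_positive            counted as a positive genetic diagnosis
  rp_candidate            recovered by the research pipeline as a candidate
  potentially_pathogenic  noticed but not diagnostic (triage stays negative)
  decoy                   designed distractor (e.g. the cancer-gene variant
                          removed at manual review)
"""

from __future__ import annotations

SUTURE_TYPES = ("Sagittal", "Metopic", "Uni/Bi-coronal",
                "Uni/Bi-lambdoidal", "Multiple", "Uncertain")

# Per-group suture-fusion marginals of the full cohort.
SUTURE_MARGINALS = {
    "syndromic": {"Sagittal": 16, "Metopic": 4, "Uni/Bi-coronal": 53,
                  "Uni/Bi-lambdoidal": 5, "Multiple": 54, "Uncertain": 31},
    "non_syndromic": {"Sagittal": 41, "Metopic": 1, "Uni/Bi-coronal": 36,
                      "Uni/Bi-lambdoidal": 10, "Multiple": 13, "Uncertain": 0},
}

# Per-group sex marginals of the full cohort (male, female).
SEX_MARGINALS = {"syndromic": (87, 76), "non_syndromic": (58, 43)}

# Panel-stage allocation: (gene, diagnosed patients, distinct P/LP variants).
# Five genes carry most panel diagnoses; four contribute one patient each.
# 139 patients, 59 distinct variants in total.
PANEL_ALLOCATION = (
    ("FGFR2", 70, 25),
    ("FGFR3", 25, 10),
    ("TWIST1", 18, 9),
    ("TCF12", 12, 6),
    ("EFNB1", 10, 5),
    ("SKI", 1, 1),
    ("RAB23", 1, 1),
    ("ERF", 1, 1),
    ("MSX2", 1, 1),
)

# The ten P/LP diagnostic findings of the exome stage: small variants first.
# inheritance pattern codes: de_novo, proband_only (parents unavailable,
# origin uncertain), maternal, maternal_x (hemizygous male, carrier mother),
# comp_het_paternal / comp_het_maternal (phased halves of a pair).
DIAGNOSTIC_SMALL_VARIANTS = (
    dict(patient="W003", sex="F", group="syndromic", suture="Multiple",
         chrom="chr5", pos=14716825, ref="TGAA", alt="T", gene="ANKH",
         transcript="NM_054027", func_class="inframe_deletion", cadd=22.1,
         ds=4, rank=1, pattern="proband_only", acmg="LP", kind="InDel"),
    dict(patient="W007", sex="F", group="syndromic", suture="Uni/Bi-lambdoidal",
         chrom="chr6", pos=26157052, ref="C", alt="CC", gene="H1-4",
         transcript="NM_005321", func_class="frameshift", cadd=None,
         ds=None, rank=1, pattern="de_novo", acmg="LP", kind="InDel"),
    dict(patient="W016", sex="F", group="syndromic", suture="Metopic",
         chrom="chr17", pos=7214668, ref="G", alt="C", gene="EIF5A",
         transcript="NM_001970.5", func_class="splicing", cadd=24.6,
         ds=None, rank=1, pattern="de_novo", acmg="LP", kind="SNV"),
    dict(patient="W033", sex="F", group="syndromic", suture="Uni/Bi-coronal",
         chrom="chr3", pos=147131159, ref="C", alt="T", gene="ZIC1",
         transcript="NM_003412", func_class="nonsense", cadd=37.0,
         ds=None, rank=1, pattern="de_novo", acmg="P", kind="SNV"),
    dict(patient="W072", sex="M", group="non_syndromic", suture="Uni/Bi-lambdoidal",
         chrom="chr11", pos=16077306, ref="G", alt="A", gene="SOX6",
         transcript="NM_033326", func_class="nonsense", cadd=36.0,
         ds=None, rank=1, pattern="de_novo", acmg="P", kind="SNV"),
    dict(patient="W083", sex="F", group="non_syndromic", suture="Multiple",
         chrom="chr1", pos=61553899, ref="C", alt="T", gene="NFIA",
         transcript="NM_005595", func_class="nonsense", cadd=38.0,
         ds=None, rank=1, pattern="de_novo", acmg="P", kind="SNV"),
    dict(patient="W097", sex="M", group="syndromic", suture="Sagittal",
         chrom="chr6", pos=157431670, ref="TCCAGTCA", alt="T", gene="ARID1B",
         transcript="NM_020732", func_class="frameshift", cadd=None,
         ds=None, rank=1, pattern="de_novo", acmg="P", kind="InDel"),
)

# ... and the three CNV deletions over the TWIST1 locus.
DIAGNOSTIC_CNVS = (
    dict(patient="W026", sex="F", group="syndromic", suture="Multiple",
         chrom="chr7", start=16572119, end=19185044, svtype="DEL",
         gene="TWIST1", inheritance="de_novo", acmg="P"),
    dict(patient="W034", sex="F", group="syndromic", suture="Uni/Bi-coronal",
         chrom="chr7", start=16127149, end=21956512, svtype="DEL",
         gene="TWIST1", inheritance="de_novo", acmg="P"),
    dict(patient="W053", sex="F", group="non_syndromic", suture="Sagittal",
         chrom="chr7", start=18498464, end=19185044, svtype="DEL",
         gene="TWIST1", inheritance="uncertain", acmg="P"),
)

# The fifteen research-pipeline candidate variants (thirteen cases; the
# IL11RA and DNAH11 cases are compound-heterozygous pairs).
CANDIDATE_VARIANTS = (
    dict(patient="W001", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chr5", pos=140966698, ref="A", alt="G", gene="DIAPH1",
         transcript="NM_005219", func_class="missense", cadd=22.9, ds=5,
         rank=1, pattern="proband_only", acmg="VUS", kind="SNV"),
    dict(patient="W008", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chrX", pos=79988961, ref="C", alt="G", gene="BRWD3",
         transcript="NM_153252", func_class="missense", cadd=26.7, ds=2,
         rank=1, pattern="maternal_x", acmg="VUS", kind="SNV"),
    dict(patient="W015", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chr4", pos=5798945, ref="C", alt="A", gene="EVC",
         transcript="NM_153717", func_class="missense", cadd=25.7, ds=2,
         rank=2, pattern="proband_only", acmg="VUS", kind="SNV"),
    dict(patient="W021", sex="M", group="syndromic", suture="Multiple",
         chrom="chr9", pos=109688611, ref="C", alt="G", gene="ZNF462",
         transcript="NM_021224", func_class="missense", cadd=20.7, ds=1,
         rank=17, pattern="proband_only", acmg="VUS", kind="SNV"),
    dict(patient="W023", sex="M", group="non_syndromic", suture="Uni/Bi-coronal",
         chrom="chr17", pos=41833050, ref="G", alt="A", gene="SOST",
         transcript="NM_025237", func_class="missense", cadd=23.5, ds=4,
         rank=1, pattern="proband_only", acmg="VUS", kind="SNV"),
    dict(patient="W038", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chr4", pos=5733339, ref="C", alt="T", gene="EVC",
         transcript="NM_153717", func_class="missense", cadd=27.1, ds=1,
         rank=3, pattern="proband_only", acmg="VUS", kind="SNV"),
    dict(patient="W041", sex="M", group="non_syndromic", suture="Uni/Bi-lambdoidal",
         chrom="chrX", pos=50378636, ref="C", alt="A", gene="SHROOM4",
         transcript="NM_020717", func_class="missense", cadd=33.0, ds=4,
         rank=18, pattern="maternal_x", acmg="VUS", kind="SNV"),
    dict(patient="W043", sex="M", group="non_syndromic", suture="Multiple",
         chrom="chrX", pos=63410654, ref="A", alt="G", gene="AMER1",
         transcript="NM_152424", func_class="missense", cadd=24.2, ds=4,
         rank=1, pattern="maternal_x", acmg="VUS", kind="SNV"),
    dict(patient="W051", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chrX", pos=50345801, ref="C", alt="A", gene="SHROOM4",
         transcript="NM_020717", func_class="missense", cadd=23.2, ds=3,
         rank=19, pattern="maternal_x", acmg="VUS", kind="SNV"),
    dict(patient="W071", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chrX", pos=148037734, ref="C", alt="T", gene="AFF2",
         transcript="NM_002025", func_class="missense", cadd=29.1, ds=5,
         rank=8, pattern="maternal_x", acmg="VUS", kind="SNV"),
    dict(patient="W085", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chrX", pos=129149626, ref="G", alt="A", gene="BCORL1",
         transcript="NM_021946", func_class="missense", cadd=21.2, ds=2,
         rank=7, pattern="maternal_x", acmg="VUS", kind="SNV"),
    dict(patient="W093", sex="F", group="non_syndromic", suture="Multiple",
         chrom="chr9", pos=34658598, ref="C", alt="G", gene="IL11RA",
         transcript="NM_001142784", func_class="missense", cadd=27.6, ds=5,
         rank=5, pattern="comp_het_paternal", acmg="VUS", kind="SNV"),
    dict(patient="W093", sex="F", group="non_syndromic", suture="Multiple",
         chrom="chr9", pos=34658577, ref="T", alt="C", gene="IL11RA",
         transcript="NM_001142784", func_class="missense", cadd=27.4, ds=5,
         rank=5, pattern="comp_het_maternal", acmg="VUS", kind="SNV"),
    dict(patient="W095", sex="M", group="syndromic", suture="Sagittal",
         chrom="chr7", pos=21726797, ref="A", alt="C", gene="DNAH11",
         transcript="NM_001277115", func_class="missense", cadd=25.1, ds=6,
         rank=1, pattern="comp_het_paternal", acmg="VUS", kind="SNV"),
    dict(patient="W095", sex="M", group="syndromic", suture="Sagittal",
         chrom="chr7", pos=21639655, ref="T", alt="C", gene="DNAH11",
         transcript="NM_001277115", func_class="missense", cadd=24.8, ds=3,
         rank=1, pattern="comp_het_maternal", acmg="VUS", kind="SNV"),
)

# Noticed by the diagnostic pipeline but not diagnostic: a likely-pathogenic
# single allele that cannot satisfy the recessive model of CDC45, and a
# de novo nonsense variant classified VUS for want of phenotype concordance
# (SNRPB is deliberately absent from the candidate-gene catalog).
POTENTIALLY_PATHOGENIC_VARIANTS = (
    dict(patient="W030", sex="M", group="syndromic", suture="Uncertain",
         chrom="chr22", pos=19479397, ref="CT", alt="C", gene="CDC45",
         transcript="NM_003504", func_class="frameshift", cadd=None, ds=None,
         rank=2, pattern="maternal", acmg="LP", kind="InDel"),
    dict(patient="W019", sex="F", group="syndromic", suture="Uncertain",
         chrom="chr20", pos=2443567, ref="C", alt="T", gene="SNRPB",
         transcript="NM_003091", func_class="nonsense", cadd=36.0, ds=None,
         rank=1, pattern="de_novo", acmg="VUS", kind="SNV"),
)

# Passes every automatic filter but is removed at manual gene review
# (cancer-associated gene); exercises the review-exclusion path.
REVIEW_EXCLUDED_VARIANTS = (
    dict(patient="W044", sex="M", group="non_syndromic", suture="Sagittal",
         chrom="chr5", pos=112175240, ref="G", alt="A", gene="APC",
         transcript="NM_000038", func_class="missense", cadd=25.3, ds=5,
         rank=4, pattern="maternal", acmg="VUS", kind="SNV"),
)

# Candidate-gene catalog sources: {source: [(symbol, models, synonyms)]}.
# A small but complete fixture: the 17 panel genes, every gene named in the
# cohort findings, plus HPO / panel-derived skull-phenotype genes.
CATALOG_SOURCES = {
    "core17": [
        ("FGFR2", "AD", ""), ("FGFR3", "AD", ""), ("TWIST1", "AD", ""),
        ("EFNB1", "XLD", ""), ("TCF12", "AD", ""), ("SKI", "AD", ""),
        ("RAB23", "AR", ""), ("FGFR1", "AD", ""), ("TGFBR2", "AD", ""),
        ("POR", "AR", ""), ("SMAD3", "AD", ""), ("ERF", "AD", ""),
        ("TGFBR1", "AD", ""), ("MSX2", "AD", ""), ("RECQL4", "AR", ""),
        ("TGFB2", "AD", ""), ("IFT43", "AR", ""),
    ],
    "literature": [
        ("ANKH", "AD", ""), ("H1-4", "AD", "HIST1H1E"), ("EIF5A", "AD", ""),
        ("ZIC1", "AD", ""), ("SOX6", "AD", ""), ("NFIA", "AD", ""),
        ("ARID1B", "AD", ""), ("CDC45", "AR", ""), ("IL11RA", "AR", ""),
        ("ZNF462", "AD", ""), ("EVC", "AR", ""), ("SOST", "AD,AR", ""),
        ("DIAPH1", "AD,AR", ""), ("APC", "AD", ""), ("MEGF8", "AR", ""),
        ("SMAD6", "AD", ""), ("BCL11B", "AD", ""), ("TFAP2B", "AD", ""),
        ("GINS2", "AR", ""),
    ],
    "hpo_craniosynostosis": [
        ("FGFR2", "AD", ""), ("TWIST1", "AD", ""), ("IL11RA", "AR", ""),
        ("ZIC1", "AD", ""), ("ERF", "AD", ""), ("RAB23", "AR", ""),
        ("CDC45", "AR", ""), ("ZNF462", "AD", ""),
    ],
    "hpo_skull": [
        ("SHROOM4", "XLR", ""), ("BRWD3", "XLR", ""), ("AMER1", "XLR", ""),
        ("AFF2", "XLR", ""), ("BCORL1", "XLR", ""), ("DNAH11", "AR", ""),
        ("SOST", "AD,AR", ""), ("EVC", "AR", ""),
    ],
    "panelapp_crs": [
        ("FGFR2", "AD", ""), ("FGFR3", "AD", ""), ("TWIST1", "AD", ""),
        ("TCF12", "AD", ""), ("EFNB1", "XLD", ""), ("IL11RA", "AR", ""),
        ("ERF", "AD", ""), ("ZIC1", "AD", ""), ("MSX2", "AD", ""),
    ],
    "panelapp_skeletal": [
        ("EVC", "AR", ""), ("SOST", "AD,AR", ""), ("RECQL4", "AR", ""),
        ("ANKH", "AD", ""), ("DIAPH1", "AD,AR", ""), ("AMER1", "XLR", ""),
    ],
}

# 1-based half-open genomic intervals used for CNV-to-gene overlap.
GENE_REGIONS = (
    ("TWIST1", "chr7", 19155091, 19157296),
    ("FGFR2", "chr10", 123237844, 123357972),
    ("MSX2", "chr5", 174151575, 174157902),
    ("SKI", "chr1", 2160134, 2241652),
)


def all_spiked_small_variants():
    """All spiked small-variant payloads with their manifest fate labels."""
    rows = []
    for v in DIAGNOSTIC_SMALL_VARIANTS:
        rows.append({**v, "fate": "cmm_positive"})
    for v in CANDIDATE_VARIANTS:
        rows.append({**v, "fate": "rp_candidate"})
    for v in POTENTIALLY_PATHOGENIC_VARIANTS:
        rows.append({**v, "fate": "potentially_pathogenic"})
    for v in REVIEW_EXCLUDED_VARIANTS:
        rows.append({**v, "fate": "decoy"})
    return rows
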