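# Methods

## Scope and data model

The package starts where variant calling and annotation end. Inputs are
per-family VCFs (GT/DP/AD), a 6-column pedigree, a per-variant annotation
table (gene, transcript, functional class, CADD, deleterious score, two
population allele frequencies, optional prioritizer rank, optional ACMG
class), a CNV interval table, a candidate-gene catalog, and a patient
table with the two-stage testing history. ACMG classification itself is
consumed as data, not re-implemented: it is the product of manual
curation, and modelling it would misrepresent the workflow.

## Quality control

Calls with total depth below `min_depth` (default 10) are removed;
remaining genotypes are re-called from the alternative-allele depth
ratio (DPRA) with hom-ref / het / hom-alt cut points at 0.3 and 0.7,
both boundaries heterozygous. Comparisons use integer cross-products
(`10*AD_alt` vs `3*DP` and `7*DP`), so boundary behaviour is exact and
recalibration is idempotent. The depth filter is per sample: a family's
site is dropped only when the *proband* fails, while a failing parent is
set to missing — this preserves parental evidence where it exists and
degrades inheritance calls to "uncertain" where it does not. A no-call
is never resurrected by recalibration: with no confident site evidence,
re-calling from two depth numbers alone would manufacture genotypes.

## Inheritance assignment

For carrier probands with two genotyped parents: het with both parents
reference is de novo (model {AD}, or {XLD} on X); het with exactly one
carrier parent is paternal/maternal with models {AD, AR} ({+XLR} on X) —
the dominant option covers incomplete penetrance, the recessive option a
carrier allele awaiting a partner; hom-alt with two carrier parents is a
biparental homozygote {AR}. Males on X are hemizygous and only the
mother is consulted: a carrier mother gives `hemizygous_maternal` {XLR}
regardless of the father's genotype. Any missing parental genotype gives
"uncertain" with the full assumed model set ({AD, AR} autosomal,
{XLD, XLR} on X); a de novo call is never emitted with a missing parent.
Mendelian-inconsistent configurations (e.g. hom-alt proband with a
hom-ref parent) are labelled uncertain rather than discarded, because
DPRA recalibration can legitimately produce them and they merit review.
Compound-heterozygote candidates are the exhaustive paternal x maternal
cross-product of heterozygous variants per gene; a variant may sit in
several pairs. Phase is parental-origin only; no read-backed phasing.

## Diagnostic triage

Positivity requires a P/LP class *and* inheritance consistency:
a single allele suffices when the variant's model set intersects a
dominant or X-linked OMIM model of the gene; recessive-only genes need a
biparental homozygote or a P/LP comp-het partner; P/LP CNVs count when
they overlap a catalog gene (1-based half-open intervals). Genes with
both dominant and recessive OMIM models accept one allele. An unresolved
("uncertain"/assumed) inheritance does not block positivity — its
assumed model set is used — because diagnostic calls in the source
workflow include cases whose parental origin could not be established.
Negative rationales are coded (`single_allele_ar_insufficient`,
`vus_only`, `no_candidate`) so cohort tallies decompose exactly.

## Research pipeline

Part one retains loss-of-function classes (frameshift, nonsense,
splicing) unconditionally and scored classes — missense *and in-frame
indels* — when DS >= 4 or CADD >= 20. Treating in-frame indels like
scored missense is a deliberate design choice: they are protein-altering
but not LoF, the same deleteriousness predictors apply, and the
workflow's diagnostic findings include a high-CADD in-frame deletion
that a LoF-or-missense-only rule would wrongly discard. Allele-frequency
ceilings are per model and per database: dominant 5e-5 (gnomAD,
allele count <= 20 of 141,456) and 5e-4 (Huabiao, <= 5 of ~5,000);
recessive/X-linked ceilings are not pinned down by the source workflow,
so the defaults 1e-3 / 5e-3 apply the same x20 relaxation to both
databases and are exposed as configuration. All threshold comparisons
are inclusive. A variant evaluated under several models survives if any
passes, and the surviving models are recorded.

Part two keeps variants the phenotype prioritizer ranked in the
proband's top 20 (across all genes, matching variant-ranked prioritizer
output), under the same frequency ceilings; unranked variants are out.
Ranks are input columns — the prioritizer is an external tool. The
intersection of the parts then needs a (synonym-aware) catalog hit and a
non-empty intersection between surviving models and the gene's OMIM
models; comp-het pairs stand or fall as a unit. The manual review step
is modelled as flags (`acmg_benign` for LB/B, `gene_review` for the
configured exclusion list, default APC), never as silent removal.

One documented inconsistency in the source material: the recovery claim
for diagnostic SNVs/indels is stated as seven in the headline summary
and nine in the results narrative. The package uses seven (the count of
diagnostic small variants actually listed); on the default cohort the
pipeline's final set additionally re-identifies the CDC45 LP single
allele, which is consistent with the narrative that one
potentially-pathogenic variant was also covered.

## Gene catalog

Built offline from flat source files (literature list, HPO-derived skull
and craniosynostosis sets, panel sets, the 17-gene core panel), unioned
with synonym-aware de-duplication; OMIM models accumulate across
sources. Entries without models match no variant. The shipped fixture
catalog contains every gene the workflow names plus the core panel; it
is a synthetic stand-in for the full 2,259-gene list, which depends on
database versions and is not reconstructable offline.

## Statistics

Yield percentages are rounded half-up to one decimal (139/264 -> 52.7);
per-trio costs half-up to whole dollars (172,305/241 -> 715). The 2x2
Fisher exact test uses scipy; two-tailed p is the point-probability
convention (sum of tables no more probable than observed), the default
of mainstream statistical software. The r x c generalization enumerates
all margin-fixed tables in exact rational arithmetic up to a bound
(default 2e6 candidate tables) and otherwise falls back to a seeded
Monte-Carlo estimate over Patefield-sampled tables with the
`(hits + 1)/(B + 1)` estimator; the method used is reported. The suture-
type test on the default cohort exceeds the enumeration bound and is
Monte-Carlo. No multiple-testing correction is applied (none is applied
in the source workflow).

The syndromic vs non-syndromic contrast on the default cohort is
[[130, 33], [19, 82]]; these group splits are fully determined by the
published aggregates (group yields 79.8% / 18.8%, exome-stage split
33 / 69, seven syndromic exome-stage diagnoses), which also fixes the
lost-to-follow-up split at 7 syndromic / 16 non-syndromic.

## Cost model

Panel-first: panel-diagnosed patients pay one panel; everyone else pays
panel + WES. WES-only: every evaluated patient pays one WES. The 23
patients lost to follow-up are excluded (N = 241). Savings are reported
per trio, as the difference of rounded per-trio means and as a
percentage of the WES-only per-trio mean. A generalized stop-on-positive
k-tier interface (`cost_tiered`) underlies both presets. Prices are
opaque per-trio inputs (defaults $315 panel, $945 WES).

## Synthetic cohort generator

The generator encodes the study conditions, not patient-level truth: the
published stage counts, per-group sex and suture-fusion marginals, the
exome-stage composition (61 male / 41 female; 33 syndromic / 69
non-syndromic; 81 trios / 21 proband-only), panel-stage diagnoses
allocated as 139 patients over 59 distinct P/LP variants in 9 genes
(five major genes led by FGFR2, four single-patient genes), and the
spiked exome-stage payloads with genotype patterns matching their stated
inheritance (de novo: het proband, reference parents; hemizygous: carrier
mother; comp-het: one allele per parent; "uncertain": parents withheld).
Spike payload values — coordinates, scores, ranks, classes — are fixed
constants; indel REF/ALT anchor bases are synthetic. Spiked allele
frequencies are 0 (novel / absent from both databases).

Decoys default to 120 per proband: log-uniform gnomAD frequency over
[1e-6, 0.5] with correlated Huabiao frequency, CADD from a low/high
mixture (means 8 and 25), functional classes spanning both sides of the
deleteriousness rule, 8% low-depth calls and 3% noisy allele balance to
exercise the QC path, and Hardy-Weinberg-ish parental genotypes with
Mendelian transmission. Decoys never collide with spike coordinates.
Decoys in catalog genes are always classed LB/B (removed at the manual-
review step) and other decoys use synthetic non-catalog symbols — the
generator models the *reviewed* endpoint of the workflow, in which no
benign or non-candidate variant survives curation, so the final
candidate list is exactly the spiked one. Spikes consume no randomness:
identical seeds give bit-identical bundles, and different seeds change
decoys but never spike payloads.

What the generator does not emulate: read-level artifacts, linkage
structure, realistic per-gene mutation spectra, batch effects in CNV
calling, or prioritizer behaviour (ranks are asserted, not computed).
Passing tests therefore demonstrate the correctness of the filtering,
triage, statistical and cost logic under the published study conditions
— not variant-calling or prioritization performance on real data.

## Numerical choices and degenerate inputs

Exact integer arithmetic at DPRA boundaries; exact rationals in the
r x c test; half-up decimal rounding for printed percentages and costs;
absent allele frequencies are 0; absent ranks fail part two; zero-depth
DPRA raises; an empty cohort is valid and yields empty outputs; per-trio
cost of an empty evaluation set raises a division error. Ties in
deterministic fills (sex, suture, design assignment) are broken by
patient-identifier order.

## Known limitations

Panel-stage variants are identifiers, not genomic payloads (only their
count and gene attribution matter downstream). The suture-type and
per-gene breakdowns are exercised on synthetic allocations; their
published per-group counts live in unavailable supplementary data, so
those specific p-values are not reproduction targets. X-chromosome
handling assumes male hemizygosity is encoded as a diploid-style
hom-alt call, the common caller convention; pseudo-autosomal regions are
not treated specially.
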