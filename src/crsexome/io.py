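"""Bundle serialization: per-family VCF 4.2, 6-column PED, TSV tables, JSON.

Every intermediate artifact is a documented plain-text table so any stage
can be replaced by an external tool's output (e.g. real prioritizer
ranks). VCFs carry GT, DP and AD per sample and round-trip the wide trio
variant table exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam

from ._util import chrom_sort_key
from .cohort import (ANNOTATION_COLUMNS, CNV_COLUMNS, PATIENT_COLUMNS,
                     VARIANT_COLUMNS, CohortBundle)
from .config import CohortConfig
from . import catalog as catalog_mod

_GT_TO_TUPLE = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1),
                "missing": (None, None)}
_TUPLE_TO_GT = {v: k for k, v in _GT_TO_TUPLE.items()}
_CONTIGS = [f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"]]


def _vcf_header(samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in _CONTIGS:
        header.contigs.add(contig)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic read depths (ref, alt)")
    for s in samples:
        header.add_sample(s)
    return header


def write_family_vcf(path: Path, family: str, variants: pd.DataFrame,
                     trio: bool) -> None:
    """Write one family's variants as VCF 4.2 (proband[, father, mother])."""
    samples = [family] + ([f"{family}_fa", f"{family}_mo"] if trio else [])
    roles = ["proband"] + (["father", "mother"] if trio else [])
    header = _vcf_header(samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in variants.itertuples(index=False):
            rec = vcf.new_record(contig=row.chrom, start=int(row.pos) - 1,
                                 alleles=(row.ref, row.alt))
            for sample, role in zip(samples, roles):
                gt = getattr(row, f"{role}_gt")
                dp = getattr(row, f"{role}_dp")
                ad = getattr(row, f"{role}_ad")
                rec.samples[sample]["GT"] = _GT_TO_TUPLE.get(gt, (None, None))
                if dp is not None and not pd.isna(dp):
                    rec.samples[sample]["DP"] = int(dp)
                    rec.samples[sample]["AD"] = (int(dp) - int(ad), int(ad))
            vcf.write(rec)


def read_family_vcf(path: Path) -> pd.DataFrame:
    """Read a family VCF back into the wide trio variant table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        family = samples[0]
        trio = len(samples) == 3
        for rec in vcf:
            row = dict(family=family, chrom=rec.chrom, pos=rec.pos,
                       ref=rec.ref, alt=rec.alts[0])
            roles = ["proband"] + (["father", "mother"] if trio else [])
            for sample, role in zip(samples, roles):
                call = rec.samples[sample]
                gt = _TUPLE_TO_GT.get(tuple(call["GT"]) if call["GT"] is not None
                                      else (None, None), "missing")
                dp = call.get("DP")
                ad = call.get("AD")
                row[f"{role}_gt"] = gt
                row[f"{role}_dp"] = None if dp is None else int(dp)
                row[f"{role}_ad"] = None if ad is None else int(ad[1])
            if not trio:
                for role in ("father", "mother"):
                    row[f"{role}_gt"] = None
                    row[f"{role}_dp"] = None
                    row[f"{role}_ad"] = None
            rows.append(row)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Serialize a cohort bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.patients, out / "patients.tsv")
    bundle.pedigree.to_csv(out / "cohort.ped", sep="\t", index=False, header=False)
    _write_tsv(bundle.annotations, out / "annotations.tsv")
    _write_tsv(bundle.cnvs, out / "cnvs.tsv")
    _write_tsv(bundle.gene_regions, out / "gene_regions.tsv")
    (out / "spike_manifest.json").write_text(
        json.dumps(bundle.manifest, indent=1, sort_keys=True) + "\n")
    (out / "config.json").write_text(
        json.dumps(vars(bundle.config), indent=1, sort_keys=True) + "\n")
    catalog_mod.write_source_files(out / "catalog", bundle.catalog_sources)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    wes = bundle.patients[bundle.patients["stage"] == "wes"]
    design = wes.set_index("patient_id")["design"].to_dict()
    for family, group in bundle.variants.groupby("family", sort=True):
        write_family_vcf(vcf_dir / f"{family}.vcf", family, group,
                         trio=design.get(family) == "trio")
    return out


def read_bundle(in_dir: str | Path) -> CohortBundle:
    """Reconstruct a cohort bundle from a serialized directory."""
    src = Path(in_dir)
    patients = pd.read_csv(src / "patients.tsv", sep="\t",
                           dtype={c: str for c in PATIENT_COLUMNS}).fillna("")
    pedigree = pd.read_csv(src / "cohort.ped", sep="\t", header=None,
                           names=["family", "individual", "father", "mother",
                                  "sex", "phenotype"], dtype=str) \
        if (src / "cohort.ped").stat().st_size else pd.DataFrame(
            columns=["family", "individual", "father", "mother", "sex", "phenotype"])
    annotations = pd.read_csv(src / "annotations.tsv", sep="\t",
                              dtype={"chrom": str, "ref": str, "alt": str})
    cnvs = pd.read_csv(src / "cnvs.tsv", sep="\t", dtype={"chrom": str})
    gene_regions = pd.read_csv(src / "gene_regions.tsv", sep="\t")
    manifest = json.loads((src / "spike_manifest.json").read_text())
    config = CohortConfig(**json.loads((src / "config.json").read_text()))
    frames = [read_family_vcf(p) for p in sorted((src / "vcf").glob("*.vcf"))]
    variants = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=VARIANT_COLUMNS)
    sources = {p.stem: p for p in sorted((src / "catalog").glob("*.tsv"))}
    bundle = CohortBundle(config=config, patients=patients, pedigree=pedigree,
                          variants=variants, annotations=annotations,
                          cnvs=cnvs, manifest=manifest,
                          gene_regions=gene_regions)
    bundle.catalog_source_paths = sources  # type: ignore[attr-defined]
    return bundle


def build_bundle_catalog(bundle: CohortBundle, source_dir: Path | None = None):
    """Build the gene catalog for a bundle (writing sources if needed)."""
    import tempfile

    if source_dir is not None:
        paths = {p.stem: p for p in sorted(Path(source_dir).glob("*.tsv"))}
        return catalog_mod.build_catalog(paths)
    with tempfile.TemporaryDirectory() as tmp:
        paths = catalog_mod.write_source_files(tmp, bundle.catalog_sources)
        return catalog_mod.build_catalog(paths)


def sort_variant_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.assign(_c=[chrom_sort_key(c) for c in df["chrom"]]).sort_values(
        ["family", "_c", "pos", "ref", "alt"], kind="stable").drop(
        columns="_c").reset_index(drop=True)
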