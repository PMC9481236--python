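"""Post-calling quality control: depth filtering and genotype recalibration.

After the standard caller output, two steps reduce false positives:

1. remove calls with total read depth below 10, and
2. re-call each remaining genotype from the depth ratio of the alternative
   allele (DPRA = alt depth / total depth): DPRA < 0.3 -> 0/0,
   0.3 <= DPRA <= 0.7 -> 0/1, DPRA > 0.7 -> 1/1.

Boundary comparisons are done in exact integer arithmetic
(10*alt vs 3*total, 10*alt vs 7*total), so 3/10 is heterozygous and no
floating-point rounding can move a call across a boundary. A family's site
is dropped only when the proband fails the depth filter; a failing parent
is set to missing so parental evidence degrades gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    genotype: str
    depth_total: int
    depth_alt: int

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype state {self.genotype!r}")
        if self.depth_total < 0:
            raise ValueError("negative total depth")
        if not 0 <= self.depth_alt <= self.depth_total:
            raise ValueError("alt depth outside [0, total depth]")


def dpra_genotype(depth_alt: int, depth_total: int) -> str:
    """Genotype from the alternative-allele depth ratio (exact arithmetic)."""
    if depth_total < 1:
        raise ValueError("DPRA undefined for zero total depth")
    ten_alt = 10 * int(depth_alt)
    if ten_alt < 3 * int(depth_total):
        return "hom_ref"
    if ten_alt > 7 * int(depth_total):
        return "hom_alt"
    return "het"


def recalibrate_genotype(call: GenotypeCall) -> GenotypeCall:
    """Replace the genotype with the DPRA-derived one; depths are unchanged.

    Missing calls stay missing — recalibration never resurrects a no-call.
    """
    if call.genotype == "missing":
        return call
    return replace(call, genotype=dpra_genotype(call.depth_alt, call.depth_total))


def depth_filter(variants: pd.DataFrame, min_depth: int = 10,
                 roles: tuple[str, ...] = ("proband", "father", "mother"),
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-sample depth filter to a wide trio variant table.

    A site is retained for a family iff the proband's depth is
    >= ``min_depth``; a parent below the threshold has its genotype set to
    missing. Returns ``(retained, report)`` where the report lists every
    action with reason ``low_depth``.
    """
    df = variants.copy()
    for role in roles:
        col = f"{role}_dp"
        if col in df.columns:
            neg = df[col].dropna() < 0
            if neg.any():
                raise ValueError(f"negative {role} depth in input")
    report_rows = []
    proband_fail = df["proband_dp"] < min_depth
    for _, row in df[proband_fail].iterrows():
        report_rows.append((row["family"], row["chrom"], row["pos"], row["ref"],
                            row["alt"], "proband", "site_removed", "low_depth"))
    df = df[~proband_fail].copy()
    for role in ("father", "mother"):
        gcol, dcol = f"{role}_gt", f"{role}_dp"
        if gcol not in df.columns:
            continue
        fail = df[dcol].notna() & (df[dcol] < min_depth) & (df[gcol] != "missing")
        for _, row in df[fail].iterrows():
            report_rows.append((row["family"], row["chrom"], row["pos"], row["ref"],
                                row["alt"], role, "genotype_set_missing", "low_depth"))
        df.loc[fail, gcol] = "missing"
    report = pd.DataFrame(report_rows, columns=[
        "family", "chrom", "pos", "ref", "alt", "sample_role", "action", "reason"])
    return df.reset_index(drop=True), report


def recalibrate_table(variants: pd.DataFrame,
                      roles: tuple[str, ...] = ("proband", "father", "mother"),
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DPRA-recalibrate every non-missing genotype in a wide variant table.

    Returns the recalibrated table and a report of calls that changed state
    (action ``genotype_recalled``).
    """
    df = variants.copy()
    report_rows = []
    for role in roles:
        gcol, dcol, acol = f"{role}_gt", f"{role}_dp", f"{role}_ad"
        if gcol not in df.columns:
            continue
        mask = df[gcol].notna() & (df[gcol] != "missing")
        if not mask.any():
            continue
        dp = df.loc[mask, dcol].astype(int)
        ad = df.loc[mask, acol].astype(int)
        if (dp < 1).any():
            raise ValueError(f"{role}: DPRA undefined for zero-depth call")
        new = pd.Series("het", index=dp.index)
        new[10 * ad < 3 * dp] = "hom_ref"
        new[10 * ad > 7 * dp] = "hom_alt"
        changed = new != df.loc[mask, gcol]
        for idx in new.index[changed]:
            row = df.loc[idx]
            report_rows.append((row["family"], row["chrom"], row["pos"], row["ref"],
                                row["alt"], role, "genotype_recalled",
                                f"{row[gcol]}->{new[idx]}"))
        df.loc[mask, gcol] = new
    report = pd.DataFrame(report_rows, columns=[
        "family", "chrom", "pos", "ref", "alt", "sample_role", "action", "reason"])
    return df, report


def run_qc(variants: pd.DataFrame, min_depth: int = 10,
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth filter then DPRA recalibration; returns (variants, report)."""
    filtered, rep1 = depth_filter(variants, min_depth=min_depth)
    recalled, rep2 = recalibrate_table(filtered)
    return recalled, pd.concat([rep1, rep2], ignore_index=True)
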