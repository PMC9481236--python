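"""End-to-end orchestration of the cohort analysis.

Stage order: simulate -> qc -> inherit -> diagnose -> research -> stats ->
cost. :func:`analyze_cohort` is the single in-memory compute path;
:func:`run_all` drives it, writes plain-text intermediates per stage (so
any stage can be re-run or replaced by an external tool's output) and
records a run manifest with per-file SHA-256 digests, identical for
identical config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortBundle, generate_cohort
from .config import RunConfig, StrategyCostSpec
from .cost import compare_strategies, cost_panel_first, cost_wes_only
from .inheritance import (annotate_partners, assign_inheritance_table,
                          pair_compound_hets)
from .io import build_bundle_catalog, write_bundle
from .qc import run_qc
from .research import run_research_pipeline
from .stats import (distinct_causal_variants, fisher_exact, fisher_rxc,
                    per_gene_positive_counts, summarize_yields)
from .triage import triage_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, str]) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True, default=str)


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, in memory."""

    bundle: CohortBundle
    qc_variants: pd.DataFrame
    qc_report: pd.DataFrame
    assigned: pd.DataFrame
    pairs: list[tuple[str, str]]
    outcomes: pd.DataFrame
    tallies: dict
    candidates: pd.DataFrame
    stats: dict
    catalog: object

    def summary(self) -> dict:
        """Compact results block, including spike-in recovery bookkeeping."""
        final = self.candidates[self.candidates["final"]]
        final_keys = set(final["key"])
        small_positive = [m for m in self.bundle.manifest
                          if m["expected_fate"] == "cmm_positive"
                          and m["record_type"] == "small_variant"]
        rp_expected = [m for m in self.bundle.manifest
                       if m["expected_fate"] == "rp_candidate"]
        return {
            "tallies": self.tallies,
            "stats": self.stats,
            "research": {
                "n_final": len(final),
                "n_final_plp": int(final["acmg_class"].isin(["P", "LP"]).sum()),
                "n_final_candidates": int((final["acmg_class"] == "VUS").sum()),
                "final_keys": sorted(final_keys),
            },
            "recovery": {
                "plp_small_spiked": len(small_positive),
                "plp_small_recovered": sum(1 for m in small_positive
                                           if m["key"] in final_keys),
                "candidates_spiked": len(rp_expected),
                "candidates_recovered": sum(1 for m in rp_expected
                                            if m["key"] in final_keys),
            },
        }


def compute_stats(outcomes: pd.DataFrame, patients: pd.DataFrame,
                  seed: int = 0) -> dict:
    """Yield summaries, per-gene contributions and group contrasts."""
    overall = summarize_yields(outcomes, patients, "overall")
    stage = summarize_yields(outcomes, patients, "stage")
    by_group = summarize_yields(outcomes, patients, "syndromic_status")
    by_suture = summarize_yields(outcomes, patients, "suture_type")
    result = {
        "overall": vars(overall[0]) if overall else None,
        "stage": {s.group: vars(s) for s in stage},
        "syndromic_status": {s.group: vars(s) for s in by_group},
        "suture_type": {s.group: vars(s) for s in by_suture},
        "distinct_plp_variants": distinct_causal_variants(outcomes),
        "per_gene_positive_patients":
            per_gene_positive_counts(outcomes).to_dict(),
    }
    groups = {s.group: s for s in by_group}
    if {"syndromic", "non_syndromic"} <= set(groups):
        s, n = groups["syndromic"], groups["non_syndromic"]
        table = [[s.n_positive, s.n_total - s.n_positive],
                 [n.n_positive, n.n_total - n.n_positive]]
        result["syndromic_vs_nonsyndromic"] = {
            "table": table,
            "p_one_tailed": fisher_exact(table, "one_tailed_greater"),
            "p_two_tailed": fisher_exact(table, "two_tailed"),
        }
    if len(by_suture) >= 2:
        table = [[s.n_positive for s in by_suture],
                 [s.n_total - s.n_positive for s in by_suture]]
        rxc = fisher_rxc(table, seed=seed)
        result["suture_type_test"] = {
            "table": table, "p": rxc.p_value, "method": rxc.method}
    return result


def analyze_cohort(config: RunConfig | None = None,
                   bundle: CohortBundle | None = None) -> AnalysisResult:
    """Run every analysis stage in memory.

    A pre-built ``bundle`` may be supplied (e.g. one read back from disk);
    otherwise the synthetic cohort is generated from the configuration.
    """
    cfg = config or RunConfig()
    cfg.validate()
    if bundle is None:
        bundle = generate_cohort(cfg.cohort)
    qc_variants, qc_report = run_qc(bundle.variants, min_depth=cfg.min_depth)
    assigned = assign_inheritance_table(qc_variants, bundle.patients)
    pairs = pair_compound_hets(assigned, bundle.annotations)
    assigned = annotate_partners(assigned, pairs)
    catalog = build_bundle_catalog(bundle)
    outcomes, tallies = triage_cohort(bundle.patients, assigned,
                                      bundle.annotations, bundle.cnvs,
                                      catalog, bundle.gene_regions)
    candidates = run_research_pipeline(assigned, bundle.annotations, catalog,
                                       cfg.thresholds,
                                       cfg.review_excluded_genes)
    stats = compute_stats(outcomes, bundle.patients, seed=cfg.cohort.seed)
    return AnalysisResult(bundle, qc_variants, qc_report, assigned, pairs,
                          outcomes, tallies, candidates, stats, catalog)


def cost_block(tallies: dict, cfg: RunConfig) -> dict:
    """Strategy cost comparison from triage tallies and configured prices."""
    spec = StrategyCostSpec(
        panel_price=cfg.cost.panel_price, wes_price=cfg.cost.wes_price,
        n_panel_pos=tallies["panel_positive"],
        n_wes_pos=tallies["wes_positive"],
        n_both_neg=tallies["both_negative"])
    pf, wo = cost_panel_first(spec), cost_wes_only(spec)
    savings = compare_strategies(spec)
    return {
        "panel_first": {**pf.group_costs, "total": pf.total,
                        "per_trio": pf.per_trio},
        "wes_only": {**wo.group_costs, "total": wo.total,
                     "per_trio": wo.per_trio},
        "savings": vars(savings),
        "n_evaluated": spec.n_evaluated,
    }


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_dir(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): _digest_file(p)
            for p in sorted(root.rglob("*")) if p.is_file()}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig | None = None, out_dir: str | Path = "results",
            ) -> tuple[RunManifest, dict]:
    """Execute every stage, write intermediates, return manifest + results."""
    cfg = config or RunConfig()
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = RunManifest(hashlib.sha256(cfg_json.encode()).hexdigest(),
                           cfg.cohort.seed)
    try:
        res = analyze_cohort(cfg)
    except Exception as exc:  # noqa: BLE001 - stage context for the CLI
        raise StageError("analysis", exc) from exc

    write_bundle(res.bundle, out / "cohort")
    manifest.add_stage("simulate", _digest_dir(out / "cohort"))

    _write_tsv(res.qc_variants, out / "qc" / "variants_qc.tsv")
    _write_tsv(res.qc_report, out / "qc" / "qc_report.tsv")
    manifest.add_stage("qc", _digest_dir(out / "qc"))

    _write_tsv(res.assigned, out / "inheritance" / "assigned.tsv")
    (out / "inheritance" / "comp_het_pairs.json").write_text(
        json.dumps(res.pairs, indent=1) + "\n")
    manifest.add_stage("inherit", _digest_dir(out / "inheritance"))

    _write_tsv(res.outcomes, out / "triage" / "outcomes.tsv")
    (out / "triage" / "tallies.json").write_text(
        json.dumps(res.tallies, indent=1, sort_keys=True) + "\n")
    manifest.add_stage("diagnose", _digest_dir(out / "triage"))

    _write_tsv(res.candidates, out / "research" / "candidates.tsv")
    manifest.add_stage("research", _digest_dir(out / "research"))

    (out / "stats").mkdir(exist_ok=True)
    (out / "stats" / "stats.json").write_text(
        json.dumps(res.stats, indent=1, sort_keys=True) + "\n")
    manifest.add_stage("stats", _digest_dir(out / "stats"))

    cost = cost_block(res.tallies, cfg)
    (out / "cost").mkdir(exist_ok=True)
    (out / "cost" / "cost.json").write_text(
        json.dumps(cost, indent=1, sort_keys=True) + "\n")
    pf, wo = cost["panel_first"], cost["wes_only"]
    _write_tsv(pd.DataFrame([
        ("panel_first", pf["panel_pos"], pf["wes_pos"], pf["both_neg"],
         pf["total"], pf["per_trio"]),
        ("wes_only", wo["panel_pos"], wo["wes_pos"], wo["both_neg"],
         wo["total"], wo["per_trio"])],
        columns=["strategy", "panel_pos", "wes_pos", "both_neg", "total",
                 "per_trio"]), out / "cost" / "cost.tsv")
    manifest.add_stage("cost", _digest_dir(out / "cost"))

    results = res.summary()
    results["cost"] = cost
    (out / "run_manifest.json").write_text(manifest.to_json() + "\n")
    (out / "results.json").write_text(
        json.dumps(results, indent=1, sort_keys=True, default=str) + "\n")
    return manifest, results
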