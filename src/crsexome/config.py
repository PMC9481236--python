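"""Configuration objects for the cohort generator, variant filters and cost model.

Defaults encode the study conditions: a 264-patient craniosynostosis cohort
with a two-stage testing history (17-gene panel, then trio exome sequencing
of panel-negative patients), the research-pipeline filter thresholds, and
the per-trio test prices used for the strategy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration violates one of its internal consistency identities."""


@dataclass
class CohortConfig:
    """Cohort composition for the synthetic generator.

    Stage counts follow the cohort's testing history: ``n_panel_pos``
    patients were diagnosed by the gene panel, ``n_wes_enrolled``
    panel-negative patients went on to exome sequencing (``n_trio`` as full
    trios, ``n_proband_only`` without parents), and ``n_lost`` panel-negative
    patients were lost to follow-up before exome sequencing.
    """

    n_total: int = 264
    n_panel_pos: int = 139
    n_wes_enrolled: int = 102
    n_wes_pos: int = 10
    n_lost: int = 23
    n_syndromic: int = 163
    n_nonsyndromic: int = 101
    n_trio: int = 81
    n_proband_only: int = 21
    # group splits per stage; defaults are the unique solution consistent
    # with the per-group diagnostic yields (79.8% / 18.8%) and the 33/69
    # syndromic/non-syndromic split of the exome stage.
    panel_pos_syndromic: int = 123
    lost_syndromic: int = 7
    n_wes_male: int = 61
    decoy_variants_per_proband: int = 120
    # log-uniform allele-frequency model for decoy variants
    decoy_af_log10_min: float = -6.0
    decoy_af_log10_max: float = -0.301
    decoy_low_depth_rate: float = 0.08
    seed: int = 1

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name.startswith("n_") and value < 0:
                raise ConfigError(f"count {name} must be non-negative, got {value}")
        checks = [
            ("n_panel_pos + n_wes_enrolled + n_lost = n_total",
             self.n_panel_pos + self.n_wes_enrolled + self.n_lost, self.n_total),
            ("n_syndromic + n_nonsyndromic = n_total",
             self.n_syndromic + self.n_nonsyndromic, self.n_total),
            ("n_trio + n_proband_only = n_wes_enrolled",
             self.n_trio + self.n_proband_only, self.n_wes_enrolled),
        ]
        for identity, lhs, rhs in checks:
            if lhs != rhs:
                raise ConfigError(f"violated identity: {identity} ({lhs} != {rhs})")
        if self.panel_pos_syndromic > self.n_panel_pos:
            raise ConfigError("panel_pos_syndromic exceeds n_panel_pos")
        if self.lost_syndromic > self.n_lost:
            raise ConfigError("lost_syndromic exceeds n_lost")
        if self.n_wes_pos > self.n_wes_enrolled:
            raise ConfigError("n_wes_pos exceeds n_wes_enrolled")
        if self.n_wes_male > self.n_wes_enrolled:
            raise ConfigError("n_wes_male exceeds n_wes_enrolled")
        wes_syndromic = self.n_syndromic - self.panel_pos_syndromic - self.lost_syndromic
        if not 0 <= wes_syndromic <= self.n_wes_enrolled:
            raise ConfigError(
                "syndromic counts leave an infeasible exome-stage split "
                f"({wes_syndromic} of {self.n_wes_enrolled})")

    @property
    def n_wes_syndromic(self) -> int:
        return self.n_syndromic - self.panel_pos_syndromic - self.lost_syndromic


@dataclass
class FilterThresholds:
    """Research-pipeline filter thresholds.

    Deleteriousness: a missense (or in-frame indel) variant is retained when
    its predictor-vote deleterious score is >= ``ds_min`` or its scaled CADD
    is >= ``cadd_min``; loss-of-function classes pass unconditionally.
    Allele-frequency ceilings are per inheritance model and per population
    database (gnomAD v2.1 and the Huabiao Han-Chinese panel); the dominant
    ceilings correspond to allele counts of <=20/141,456 and <=5/~5,000.
    ``rank_max`` keeps the top phenotype-prioritizer variants per proband.
    """

    cadd_min: float = 20.0
    ds_min: int = 4
    af_ad_gnomad: float = 0.00005
    af_ad_huabiao: float = 0.0005
    af_recessive_gnomad: float = 0.001
    af_recessive_huabiao: float = 0.005
    rank_max: int = 20

    def validate(self) -> None:
        for name in ("af_ad_gnomad", "af_ad_huabiao",
                     "af_recessive_gnomad", "af_recessive_huabiao"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.rank_max < 1:
            raise ConfigError("rank_max must be >= 1")
        if self.ds_min < 0:
            raise ConfigError("ds_min must be >= 0")


@dataclass
class StrategyCostSpec:
    """Per-trio test prices and stage-outcome counts for the cost comparison.

    The three groups partition the patients who completed testing:
    panel-diagnosed, exome-diagnosed (panel-negative), and negative by both.
    Patients lost to follow-up are excluded from cost evaluation.
    """

    panel_price: float = 315.0
    wes_price: float = 945.0
    n_panel_pos: int = 139
    n_wes_pos: int = 10
    n_both_neg: int = 92

    def validate(self) -> None:
        if self.panel_price < 0 or self.wes_price < 0:
            raise ConfigError("prices must be non-negative")
        for name in ("n_panel_pos", "n_wes_pos", "n_both_neg"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return self.n_panel_pos + self.n_wes_pos + self.n_both_neg


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cost: StrategyCostSpec = field(default_factory=StrategyCostSpec)
    min_depth: int = 10
    review_excluded_genes: tuple[str, ...] = ("APC",)

    def validate(self) -> None:
        self.cohort.validate()
        self.thresholds.validate()
        self.cost.validate()
        if self.min_depth < 0:
            raise ConfigError("min_depth must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["review_excluded_genes"] = list(self.review_excluded_genes)
        return d


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; missing sections fall back to defaults."""
    cfg = RunConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw:
            cfg.cohort = CohortConfig(**raw["cohort"])
        if "thresholds" in raw:
            cfg.thresholds = FilterThresholds(**raw["thresholds"])
        if "cost" in raw:
            cfg.cost = StrategyCostSpec(**raw["cost"])
        if "min_depth" in raw:
            cfg.min_depth = int(raw["min_depth"])
        if "review_excluded_genes" in raw:
            cfg.review_excluded_genes = tuple(raw["review_excluded_genes"])
    if seed is not None:
        cfg.cohort.seed = int(seed)
    cfg.validate()
    return cfg
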