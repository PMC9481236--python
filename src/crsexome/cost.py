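"""Cost model for tiered genetic-testing strategies.

Compares "Panel-first" (gene panel for everyone; exome sequencing only for
panel-negative patients) against "WES-only" at equal diagnostic yield,
given per-trio prices and the three stage-outcome groups: panel-diagnosed,
exome-diagnosed, and negative by both. Per-trio means are rounded half-up
to whole currency units. A generalized k-tier interface is provided; the
two published strategies are presets over it.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import round_half_up
from .config import StrategyCostSpec


@dataclass(frozen=True)
class CostBreakdown:
    strategy: str
    group_costs: dict[str, float]  # panel_pos / wes_pos / both_neg totals
    total: float
    per_trio: float  # mean cost per trio, whole currency units


@dataclass(frozen=True)
class SavingsReport:
    absolute_per_trio: float
    percent_saved: float
    cheaper_strategy: str


def cost_tiered(tier_prices: list[float], stop_counts: list[int],
                n_never_positive: int) -> tuple[list[float], float]:
    """Generalized stop-on-positive tiered strategy.

    ``tier_prices[i]`` is the price of test i; ``stop_counts[i]`` patients
    are diagnosed at tier i (and pay tiers 0..i); ``n_never_positive``
    patients run every tier. Returns per-group totals (groups ordered by
    stopping tier, never-positive last) and the grand total.
    """
    if len(tier_prices) != len(stop_counts):
        raise ValueError("tier_prices and stop_counts must align")
    cumulative = []
    acc = 0.0
    for p in tier_prices:
        acc += p
        cumulative.append(acc)
    groups = [n * cumulative[i] for i, n in enumerate(stop_counts)]
    groups.append(n_never_positive * (cumulative[-1] if cumulative else 0.0))
    return groups, sum(groups)


def _per_trio(total: float, n: int) -> float:
    if n == 0:
        raise ZeroDivisionError("per-trio mean undefined for zero evaluated patients")
    return round_half_up(total / n, 0)


def cost_panel_first(spec: StrategyCostSpec | None = None) -> CostBreakdown:
    """Panel for everyone; exome sequencing only after a negative panel."""
    spec = spec or StrategyCostSpec()
    spec.validate()
    groups, total = cost_tiered([spec.panel_price, spec.wes_price],
                                [spec.n_panel_pos, spec.n_wes_pos],
                                spec.n_both_neg)
    return CostBreakdown(
        "panel_first",
        {"panel_pos": groups[0], "wes_pos": groups[1], "both_neg": groups[2]},
        total, _per_trio(total, spec.n_evaluated))


def cost_wes_only(spec: StrategyCostSpec | None = None) -> CostBreakdown:
    """Every evaluated patient gets exome sequencing directly."""
    spec = spec or StrategyCostSpec()
    spec.validate()
    groups = {
        "panel_pos": spec.n_panel_pos * spec.wes_price,
        "wes_pos": spec.n_wes_pos * spec.wes_price,
        "both_neg": spec.n_both_neg * spec.wes_price,
    }
    total = sum(groups.values())
    return CostBreakdown("wes_only", groups, total,
                         _per_trio(total, spec.n_evaluated))


def compare_strategies(spec: StrategyCostSpec | None = None) -> SavingsReport:
    """Per-trio saving of Panel-first relative to WES-only.

    Absolute saving is the difference of the (rounded) per-trio means;
    percentage is relative to the WES-only per-trio mean, half-up to one
    decimal.
    """
    spec = spec or StrategyCostSpec()
    panel_first = cost_panel_first(spec)
    wes_only = cost_wes_only(spec)
    absolute = wes_only.per_trio - panel_first.per_trio
    percent = (round_half_up(100.0 * absolute / wes_only.per_trio, 1)
               if wes_only.per_trio else 0.0)
    cheaper = "panel_first" if absolute >= 0 else "wes_only"
    return SavingsReport(absolute, percent, cheaper)
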