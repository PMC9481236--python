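"""Diagnostic-yield summaries and exact contingency-table tests.

Yield percentages are reported half-up to one decimal, the convention of
the printed clinical summaries (139/264 -> 52.7). The 2x2 Fisher exact
test delegates to scipy (two-tailed uses the point-probability method);
the r-by-c generalization enumerates all tables with the observed margins
exactly in rational arithmetic, falling back to a seeded Monte-Carlo
estimate (Patefield sampling) when the enumeration would be too large.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial, prod

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from ._util import round_half_up


@dataclass(frozen=True)
class YieldSummary:
    group: str
    n_total: int
    n_positive: int
    yield_percent: float


@dataclass(frozen=True)
class FisherRxCResult:
    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    n_tables: int = 0


def summarize_yields(outcomes: pd.DataFrame, patients: pd.DataFrame,
                     grouping: str = "overall") -> list[YieldSummary]:
    """Per-group diagnostic yields over the whole cohort.

    ``grouping`` is one of ``overall``, ``stage``, ``syndromic_status`` or
    ``suture_type``. Stage yields use the whole cohort as denominator (the
    panel solved 139/264, the exome stage added 10/264).
    """
    if outcomes.empty:
        return []
    merged = outcomes.merge(patients[["patient_id", "group", "suture"]],
                            on="patient_id", how="left")
    n_all = len(merged)
    positive = merged["status"] == "positive"

    def summary(label, n_total, n_pos):
        pct = round_half_up(100.0 * n_pos / n_total, 1) if n_total else 0.0
        return YieldSummary(label, int(n_total), int(n_pos), pct)

    if grouping == "overall":
        return [summary("overall", n_all, positive.sum())]
    if grouping == "stage":
        return [
            summary("panel", n_all, (positive & (merged["stage"] == "panel")).sum()),
            summary("wes", n_all, (positive & (merged["stage"] == "wes")).sum()),
        ]
    if grouping == "syndromic_status":
        col = "group"
    elif grouping == "suture_type":
        col = "suture"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = []
    for label, sub in merged.groupby(col, sort=True):
        out.append(summary(str(label), len(sub), (sub["status"] == "positive").sum()))
    return out


def per_gene_positive_counts(outcomes: pd.DataFrame) -> pd.Series:
    """Distinct positive patients per causal gene, descending."""
    rows = []
    pos = outcomes[outcomes["status"] == "positive"]
    for r in pos.itertuples(index=False):
        for gene in str(r.causal_genes).split(";"):
            if gene:
                rows.append((gene, r.patient_id))
    if not rows:
        return pd.Series(dtype=int)
    df = pd.DataFrame(rows, columns=["gene", "patient_id"]).drop_duplicates()
    return df.groupby("gene")["patient_id"].nunique().sort_values(
        ascending=False, kind="stable")


def distinct_causal_variants(outcomes: pd.DataFrame) -> int:
    """Count of distinct causal P/LP variants across both stages."""
    keys = set()
    for v in outcomes.loc[outcomes["status"] == "positive", "causal_variants"]:
        keys.update(k for k in str(v).split(";") if k)
    return len(keys)


def _validate_counts(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(int)
    return arr


def fisher_exact(table, sidedness: str = "two_tailed") -> float:
    """Fisher's exact test on a 2x2 table.

    ``sidedness``: ``one_tailed_greater`` (association in the direction of
    the first cell), ``one_tailed_less``, or ``two_tailed`` (sum of point
    probabilities no larger than the observed one).
    """
    arr = _validate_counts(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    alternative = {"one_tailed_greater": "greater", "one_tailed_less": "less",
                   "two_tailed": "two-sided"}.get(sidedness)
    if alternative is None:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(sps.fisher_exact(arr, alternative=alternative).pvalue)


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    r = len(row_margins)

    def fill(rows_left, cols_left, acc):
        if rows_left == 1:
            yield acc + [list(cols_left)]
            return
        row_total = row_margins[r - rows_left]

        def fill_row(j, remaining, row_acc, cols):
            if j == len(cols) - 1:
                if remaining <= cols[j]:
                    new_cols = list(cols)
                    new_cols[j] -= remaining
                    yield row_acc + [remaining], new_cols
                return
            for v in range(min(remaining, cols[j]) + 1):
                new_cols = list(cols)
                new_cols[j] -= v
                yield from fill_row(j + 1, remaining - v, row_acc + [v], new_cols)

        for row, new_cols in fill_row(0, row_total, [], list(cols_left)):
            yield from fill(rows_left - 1, new_cols, acc + [row])

    yield from fill(r, list(col_margins), [])


def _table_prob(cells, row_margins, col_margins, n) -> Fraction:
    num = prod(factorial(m) for m in row_margins) * \
        prod(factorial(m) for m in col_margins)
    den = factorial(n) * prod(factorial(c) for row in cells for c in row)
    return Fraction(num, den)


def _enumeration_size_bound(row_margins, col_margins) -> int:
    r = len(row_margins)
    return prod(comb(c + r - 1, r - 1) for c in col_margins)


def fisher_rxc(table, enumeration_bound: int = 2_000_000,
               monte_carlo: bool = True, n_samples: int = 200_000,
               seed: int = 0) -> FisherRxCResult:
    """Exact conditional test of independence on an r-by-c table.

    The p-value is the total probability, under the multivariate
    hypergeometric distribution with the observed margins, of tables no
    more probable than the observed one. Enumeration is exact (rational
    arithmetic); above ``enumeration_bound`` candidate tables a seeded
    Monte-Carlo estimate over Patefield-sampled tables is returned instead
    (or a capability error if ``monte_carlo`` is disabled).
    """
    arr = _validate_counts(table)
    rows = arr.sum(axis=1).tolist()
    cols = arr.sum(axis=0).tolist()
    n = int(arr.sum())
    if n == 0:
        return FisherRxCResult(1.0, "enumeration", 1)
    if _enumeration_size_bound(rows, cols) <= enumeration_bound:
        p_obs = _table_prob(arr.tolist(), rows, cols, n)
        p = Fraction(0)
        count = 0
        for cells in _enumerate_tables(rows, cols):
            count += 1
            pt = _table_prob(cells, rows, cols, n)
            if pt <= p_obs:
                p += pt
        return FisherRxCResult(float(p), "enumeration", count)
    if not monte_carlo:
        raise ValueError("table too large for exact enumeration and "
                         "Monte-Carlo estimation is disabled")
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(rows, cols, seed=rng)
    samples = sampler.rvs(n_samples)
    const = (sum(gammaln(m + 1) for m in rows) + sum(gammaln(m + 1) for m in cols)
             - gammaln(n + 1))
    logp = const - gammaln(samples + 1).sum(axis=(1, 2))
    logp_obs = const - gammaln(arr + 1).sum()
    hits = int(np.sum(logp <= logp_obs + 1e-7))
    return FisherRxCResult((hits + 1) / (n_samples + 1), "monte_carlo", n_samples)
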