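"""Yield summaries and exact contingency-table tests.

The Fisher implementations are validated against an independent
exact-rational hypergeometric oracle written here (full enumeration with
``fractions.Fraction``), not against another library route.
"""

from fractions import Fraction
from itertools import product
from math import comb, factorial, prod

import numpy as np
import pandas as pd
import pytest

from crsexome.stats import (FisherRxCResult, fisher_exact, fisher_rxc,
                            summarize_yields)


# --- independent oracle -------------------------------------------------

def hypergeom_pmf(k, n_pop, k_pop, n_draw) -> Fraction:
    return Fraction(comb(k_pop, k) * comb(n_pop - k_pop, n_draw - k),
                    comb(n_pop, n_draw))


def oracle_2x2(a, b, c, d):
    """All point probabilities for tables with the margins of [[a,b],[c,d]]."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return {k: hypergeom_pmf(k, n, col1, row1) for k in range(lo, hi + 1)}


def oracle_p(a, b, c, d, sidedness):
    probs = oracle_2x2(a, b, c, d)
    if sidedness == "one_tailed_greater":
        return sum(p for k, p in probs.items() if k >= a)
    if sidedness == "one_tailed_less":
        return sum(p for k, p in probs.items() if k <= a)
    return sum(p for p in probs.values() if p <= probs[a])


# --- 2x2 ----------------------------------------------------------------

def test_point_probabilities_sum_to_one():
    """Hypergeometric point masses over all margin-fixed tables sum to 1."""
    for a, b, c, d in [(2, 0, 0, 2), (5, 10, 15, 30), (20, 10, 13, 17),
                       (1, 1, 1, 1), (0, 7, 9, 0)]:
        assert sum(oracle_2x2(a, b, c, d).values()) == 1


def test_balanced_diagonal_one_tailed_is_one_sixth():
    p = fisher_exact([[2, 0], [0, 2]], "one_tailed_greater")
    assert oracle_p(2, 0, 0, 2, "one_tailed_greater") == Fraction(1, 6)
    assert p == pytest.approx(1 / 6, rel=1e-12)


@pytest.mark.parametrize("a,b", [(1, 1), (3, 7), (12, 5)])
def test_identical_rows_two_tailed_is_one(a, b):
    assert fisher_exact([[a, b], [a, b]], "two_tailed") == pytest.approx(1.0)


@pytest.mark.parametrize("table", [
    [[2, 0], [0, 2]], [[5, 1], [2, 7]], [[10, 3], [4, 12]],
    [[0, 5], [5, 0]], [[8, 8], [8, 8]], [[1, 9], [11, 2]],
])
@pytest.mark.parametrize("sidedness", ["one_tailed_greater",
                                       "one_tailed_less", "two_tailed"])
def test_fisher_matches_exact_enumeration_oracle(table, sidedness):
    (a, b), (c, d) = table
    expected = float(oracle_p(a, b, c, d, sidedness))
    assert fisher_exact(table, sidedness) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("table", [[[5, 1], [2, 7]], [[4, 4], [6, 2]]])
def test_tail_decomposition_identity(table):
    """greater-tail + less-tail - point probability = 1."""
    (a, b), (c, d) = table
    point = float(oracle_2x2(a, b, c, d)[a])
    total = fisher_exact(table, "one_tailed_greater") + \
        fisher_exact(table, "one_tailed_less") - point
    assert total == pytest.approx(1.0, rel=1e-9)


def test_fisher_rejects_negative_and_non_2x2():
    with pytest.raises(ValueError):
        fisher_exact([[1, -2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]])


# --- r x c --------------------------------------------------------------

def oracle_rxc(table):
    """Independent brute force: iterate the full cell product space."""
    arr = np.asarray(table)
    rows, cols = arr.sum(axis=1), arr.sum(axis=0)
    n = int(arr.sum())

    def table_prob(cells):
        num = prod(factorial(int(m)) for m in rows) * \
            prod(factorial(int(m)) for m in cols)
        den = factorial(n) * prod(factorial(int(c)) for c in np.ravel(cells))
        return Fraction(num, den)

    p_obs = table_prob(arr)
    total = Fraction(0)
    r, c = arr.shape
    ranges = [range(min(rows[i], cols[j]) + 1)
              for i in range(r - 1) for j in range(c - 1)]
    for inner in product(*ranges):
        cells = np.zeros((r, c), dtype=int)
        cells[:r - 1, :c - 1] = np.reshape(inner, (r - 1, c - 1))
        cells[:r - 1, c - 1] = rows[:r - 1] - cells[:r - 1, :c - 1].sum(axis=1)
        cells[r - 1, :] = cols - cells[:r - 1, :].sum(axis=0)
        if (cells >= 0).all() and table_prob(cells) <= p_obs:
            total += table_prob(cells)
    return float(total)


def test_rxc_on_2x2_equals_two_tailed_fisher():
    table = [[5, 1], [2, 7]]
    res = fisher_rxc(table)
    assert res.method == "enumeration"
    assert res.p_value == pytest.approx(fisher_exact(table, "two_tailed"),
                                        rel=1e-9)


def test_rxc_uniform_table_is_one():
    assert fisher_rxc([[1, 1, 1], [1, 1, 1]]).p_value == pytest.approx(1.0)


@pytest.mark.parametrize("table", [
    [[5, 0, 0], [0, 5, 5]],
    [[3, 1, 2], [0, 4, 1]],
    [[2, 2], [2, 2], [4, 0]],
])
def test_rxc_matches_brute_force_oracle(table):
    res = fisher_rxc(table)
    assert res.method == "enumeration"
    assert res.p_value == pytest.approx(oracle_rxc(table), rel=1e-9)


def test_rxc_monte_carlo_agrees_with_enumeration():
    table = [[5, 0, 0], [0, 5, 5]]
    exact = fisher_rxc(table).p_value
    mc = fisher_rxc(table, enumeration_bound=1, monte_carlo=True,
                    n_samples=40_000, seed=11)
    assert mc.method == "monte_carlo"
    assert mc.p_value == pytest.approx(exact, abs=0.01)


def test_rxc_monte_carlo_is_seed_deterministic():
    table = [[5, 0, 0], [0, 5, 5]]
    kwargs = dict(enumeration_bound=1, n_samples=5_000)
    assert fisher_rxc(table, seed=3, **kwargs).p_value == \
        fisher_rxc(table, seed=3, **kwargs).p_value


def test_rxc_capability_error_without_monte_carlo():
    with pytest.raises(ValueError, match="too large"):
        fisher_rxc([[50, 60, 70], [80, 90, 100]], enumeration_bound=10,
                   monte_carlo=False)


def test_rxc_result_type():
    assert isinstance(fisher_rxc([[1, 0], [0, 1]]), FisherRxCResult)


# --- yields -------------------------------------------------------------

def _outcomes(rows):
    return pd.DataFrame(rows, columns=["patient_id", "stage", "status",
                                       "causal_variants", "causal_genes",
                                       "rationale"])


def _patients(rows):
    return pd.DataFrame(rows, columns=["patient_id", "group", "suture"])


def test_yield_rounding_is_half_up():
    outcomes = _outcomes(
        [(f"P{i}", "panel", "positive" if i < 139 else "negative", "v", "g", "")
         for i in range(264)])
    patients = _patients([(f"P{i}", "syndromic", "Sagittal")
                          for i in range(264)])
    overall = summarize_yields(outcomes, patients, "overall")[0]
    assert overall.yield_percent == 52.7
    assert (overall.n_positive, overall.n_total) == (139, 264)


def test_single_positive_patient_is_100_percent():
    outcomes = _outcomes([("P1", "wes", "positive", "v", "g", "")])
    patients = _patients([("P1", "syndromic", "Sagittal")])
    assert summarize_yields(outcomes, patients, "overall")[0].yield_percent \
        == 100.0


def test_empty_cohort_gives_empty_summaries():
    assert summarize_yields(_outcomes([]), _patients([]), "overall") == []


def test_group_yields_recompute_from_raw_tallies(analysis):
    for grouping in ("overall", "stage", "syndromic_status", "suture_type"):
        for s in summarize_yields(analysis.outcomes, analysis.bundle.patients,
                                  grouping):
            assert 0 <= s.n_positive <= s.n_total
            if s.n_total:
                expected = round(100.0 * s.n_positive / s.n_total, 1)
                assert abs(s.yield_percent - expected) <= 0.05
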