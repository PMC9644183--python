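"""Ranks, quintiles, concentration index and slope index of inequality.

The CIX covariance formula is checked against an independent brute-force
pairwise (Gini-type) computation, and the SII against closed-form weighted
least squares, on exhaustively small weighted instances.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dietiq.equity import (assign_quintiles, attach_expenditure_ranks,
                           concentration_index, fractional_rank,
                           per_capita_expenditure, slope_index,
                           slope_index_from_quintiles)
from dietiq.errors import (DegenerateDistributionError, EstimationError,
                           UndefinedIndexError)


# --- independent oracles ----------------------------------------------------

def brute_ranks(values, weights):
    """Midpoint ranks by an explicit cumulative-weight walk."""
    order = sorted(range(len(values)), key=lambda i: (values[i], i))
    total = sum(weights)
    ranks = [0.0] * len(values)
    cum = 0.0
    for i in order:
        ranks[i] = (cum + weights[i] / 2.0) / total
        cum += weights[i]
    return ranks


def brute_cix(y, ranks, weights):
    """Pairwise Gini-type concentration index, scaled to -100..100."""
    total = sum(weights)
    mu = sum(w * v for w, v in zip(weights, y)) / total
    acc = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            sgn = int(ranks[i] > ranks[j]) - int(ranks[i] < ranks[j])
            acc += weights[i] * weights[j] * (y[i] - y[j]) * sgn
    return 100.0 * acc / (2.0 * mu * total * total)


def brute_wls_slope(y, x, weights):
    xb = sum(w * v for w, v in zip(weights, x)) / sum(weights)
    yb = sum(w * v for w, v in zip(weights, y)) / sum(weights)
    num = sum(w * (xi - xb) * (yi - yb) for w, xi, yi in zip(weights, x, y))
    den = sum(w * (xi - xb) ** 2 for w, xi in zip(weights, x))
    return num / den


# --- fractional ranks & quintiles ------------------------------------------

class TestRanks:
    def test_five_equal_weights(self):
        r = fractional_rank(np.arange(5.0), np.ones(5))
        np.testing.assert_allclose(r, [0.1, 0.3, 0.5, 0.7, 0.9])

    def test_single_record(self):
        np.testing.assert_allclose(fractional_rank([3.0], [2.0]), [0.5])

    def test_unequal_weights(self):
        r = fractional_rank([1.0, 2.0], [1.0, 3.0])
        np.testing.assert_allclose(r, [0.125, 0.625])

    @given(
        vals=hst.lists(hst.integers(0, 50), min_size=1, max_size=8, unique=True),
        seed=hst.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_cumulative_walk(self, vals, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.2, 3.0, len(vals))
        got = fractional_rank(np.array(vals, float), w)
        np.testing.assert_allclose(got, brute_ranks(vals, list(w)), atol=1e-12)


class TestQuintiles:
    def test_five_distinct_equal_weights_one_each(self):
        q, _ = assign_quintiles(np.arange(5.0), np.ones(5))
        assert list(q) == ["Q1", "Q2", "Q3", "Q4", "Q5"]

    def test_weight_midpoint_rule(self):
        # weights (1,1,2): the heavy record spans Q3-Q5 mass, midpoint in Q4
        q, r = assign_quintiles(np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, 1.0, 2.0]))
        assert list(q) == ["Q1", "Q2", "Q4"]
        np.testing.assert_allclose(r, [0.125, 0.375, 0.75])

    def test_degenerate_distribution(self):
        with pytest.raises(DegenerateDistributionError):
            assign_quintiles(np.ones(6), np.ones(6))

    def test_pooled_assignment_shifts_with_other_round(self, small_bundle, design):
        ranked = attach_expenditure_ranks(
            small_bundle["persons"], small_bundle["households"], design)
        # a fixed expenditure ranks lower once pooled with the richer round
        r1 = ranked[ranked["round"] == "2011"]
        med_2011 = r1["per_capita_expenditure"].median()
        pooled_rank = ranked.loc[
            (ranked["per_capita_expenditure"] - med_2011).abs().idxmin(),
            "fractional_rank"]
        assert pooled_rank < 0.5  # 2018 is richer, so the 2011 median sits below


class TestPerCapita:
    def test_examples(self):
        hh = pd.DataFrame({"monthly_expenditure": [4000.0, 1500.0, 3000.0],
                           "n_members": [4, 1, 3]})
        np.testing.assert_allclose(per_capita_expenditure(hh),
                                   [1000.0, 1500.0, 1000.0])


# --- concentration index ----------------------------------------------------

class TestCIX:
    def test_constant_outcome_zero(self):
        r = fractional_rank(np.arange(5.0), np.ones(5))
        est = concentration_index(np.full(5, 3.0), r, np.ones(5))
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_poorest_only_is_minus_80(self):
        y = np.array([1.0, 0, 0, 0, 0])
        r = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        est = concentration_index(y, r, np.ones(5))
        assert est.value == pytest.approx(-80.0, abs=1e-12)

    def test_rank_reversal_flips_sign(self):
        rng = np.random.default_rng(3)
        y = rng.random(12)
        w = rng.uniform(0.5, 2.0, 12)
        r = fractional_rank(rng.random(12), w)
        a = concentration_index(y, r, w).value
        b = concentration_index(y, 1.0 - r, w).value
        assert a == pytest.approx(-b, abs=1e-12)

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedIndexError):
            concentration_index(np.zeros(4), np.linspace(0.1, 0.9, 4), np.ones(4))

    @given(
        n=hst.integers(2, 8),
        seed=hst.integers(0, 100_000),
    )
    @settings(max_examples=80, deadline=None)
    def test_binary_bound(self, n, seed):
        """|CIX| <= 100 (1 - mu) for a binary outcome of prevalence mu."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n).astype(float)
        if y.sum() == 0:
            y[0] = 1.0
        w = rng.uniform(0.2, 3.0, n)
        r = fractional_rank(rng.permutation(n).astype(float), w)
        mu = np.average(y, weights=w)
        est = concentration_index(y, r, w)
        assert abs(est.value) <= 100.0 * (1.0 - mu) + 1e-9


# --- slope index ------------------------------------------------------------

class TestSII:
    def test_perfect_gradient(self):
        r = np.linspace(0.05, 0.95, 20)
        est = slope_index(100.0 * r, r, np.ones(20))
        assert est.value == pytest.approx(100.0, abs=1e-9)

    def test_quintile_prevalence_slope_minus_50(self):
        prev = np.array([60.0, 50.0, 40.0, 30.0, 20.0])
        assert slope_index_from_quintiles(prev) == pytest.approx(-50.0, abs=1e-12)
        # same answer from the individual-level route on 5 points
        est = slope_index(prev, np.arange(0.1, 1.0, 0.2), np.ones(5))
        assert est.value == pytest.approx(-50.0, abs=1e-9)

    def test_degenerate_ranks_rejected(self):
        with pytest.raises(EstimationError):
            slope_index(np.ones(4), np.full(4, 0.5), np.ones(4))

    def test_null_gradient_near_zero(self):
        rng = np.random.default_rng(11)
        n = 4000
        r = fractional_rank(rng.random(n), np.ones(n))
        y = 100.0 * (rng.random(n) < 0.4)
        est = slope_index(y, r, np.ones(n))
        assert abs(est.value) < 2.0 * est.se + 1e-9 or abs(est.value) < 5.0


# --- oracle equivalence -----------------------------------------------------

@given(
    n=hst.integers(2, 8),
    seed=hst.integers(0, 100_000),
)
@settings(max_examples=100, deadline=None)
def test_cix_and_sii_match_bruteforce(n, seed):
    """Covariance-formula CIX == pairwise computation; SII == closed-form WLS."""
    rng = np.random.default_rng(seed)
    vals = rng.permutation(n).astype(float)  # distinct -> unambiguous ranks
    w = rng.uniform(0.2, 3.0, n)
    y = rng.uniform(0.0, 1.0, n)
    r = fractional_rank(vals, w)
    got = concentration_index(y, r, w).value
    want = brute_cix(list(y), list(r), list(w))
    assert got == pytest.approx(want, abs=1e-12)
    if n >= 3 and np.ptp(r) > 0:
        got_s = slope_index(100.0 * y, r, w).value
        want_s = brute_wls_slope(list(100.0 * y), list(r), list(w))
        assert got_s == pytest.approx(want_s, abs=1e-9)
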