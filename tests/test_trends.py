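"""Percent changes, geometric-mean ratios, adjusted Wald test, cell summaries."""

import numpy as np
import pandas as pd
import pytest

from dietiq.core import SurveyDesign
from dietiq.errors import EstimationError, UndefinedChangeError
from dietiq.trends import (adjusted_wald, intake_ratio, pct_change,
                           round_half_away, significance_stars,
                           summarize_cells, weighted_median)


class TestPctChange:
    @pytest.mark.parametrize("v0, v1, expected", [
        (47.5, 69.5, 46.3),     # minimum dietary diversity, young boys
        (10.2, 24.3, 138.2),    # egg consumption, school-age boys
        (4.1, 4.0, -2.4),       # household size
        (1554.0, 1803.0, 16.0), # per-capita expenditure
    ])
    def test_published_style_rounding(self, v0, v1, expected):
        assert round_half_away(pct_change(v0, v1), 1) == expected

    def test_identity(self):
        assert pct_change(12.3, 12.3) == 0.0

    def test_zero_baseline_undefined(self):
        with pytest.raises(UndefinedChangeError):
            pct_change(0.0, 5.0)

    def test_half_away_from_zero(self):
        assert round_half_away(12.25, 1) == 12.3
        assert round_half_away(-12.25, 1) == -12.3
        assert round_half_away(87.2549, 1) == 87.3


def test_significance_stars():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.2) == ""


class TestIntakeRatio:
    def _two_rounds(self, v1, v2):
        n1, n2 = len(v1), len(v2)
        return (np.concatenate([v1, v2]),
                np.array(["2011"] * n1 + ["2018"] * n2),
                np.ones(n1 + n2),
                np.array([f"P{i % 4}" for i in range(n1 + n2)]))

    def test_exact_multiplicative_shift(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(7.5, 0.3, 400)
        v, r, w, psu = self._two_rounds(base, 0.9 * base)
        res = intake_ratio(v, r, w, psu, ("2011", "2018"))
        assert res.ratio == pytest.approx(0.90, abs=1e-9)

    def test_ratio_is_geometric_mean_ratio(self):
        rng = np.random.default_rng(1)
        v1 = rng.lognormal(7.0, 0.4, 300)
        v2 = rng.lognormal(6.9, 0.5, 350)
        w = rng.uniform(0.5, 2.0, 650)
        v, r, _, psu = self._two_rounds(v1, v2)
        res = intake_ratio(v, r, w, psu, ("2011", "2018"))
        gm1 = np.exp(np.average(np.log(v1), weights=w[:300]))
        gm2 = np.exp(np.average(np.log(v2), weights=w[300:]))
        assert res.ratio == pytest.approx(gm2 / gm1, rel=1e-9)

    def test_null_distributions_ratio_one(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(7.5, 0.3, 2000)
        v, r, w, psu = self._two_rounds(base[:1000], base[1000:])
        res = intake_ratio(v, r, w, psu, ("2011", "2018"))
        assert res.ci_low < 1.0 < res.ci_high
        assert res.p_value > 0.05

    def test_zero_intakes_excluded_and_counted(self):
        v = np.array([100.0, 0.0, 90.0, 110.0])
        r = np.array(["2011", "2011", "2018", "2018"])
        res = intake_ratio(v, r, np.ones(4), np.array(["a", "b", "a", "b"]),
                           ("2011", "2018"))
        assert res.n_excluded_zero == 1

    def test_empty_round_rejected(self):
        v = np.array([100.0, 0.0])
        r = np.array(["2011", "2018"])
        with pytest.raises(EstimationError):
            intake_ratio(v, r, np.ones(2), np.array(["a", "b"]), ("2011", "2018"))


class TestAdjustedWald:
    def test_identical_prevalences_p_one(self):
        y = np.tile([1.0, 0.0, 1.0, 0.0], 10)
        psu = np.tile(["A", "A", "B", "B"], 10)
        rounds = np.array((["2011"] * 4 + ["2018"] * 4) * 5)
        d, p = adjusted_wald(y, rounds, np.ones(40), psu, ("2011", "2018"))
        assert d == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_programmed_jump_detected(self):
        rng = np.random.default_rng(5)
        n_psu, m = 80, 30
        psu = np.repeat([f"P{i}" for i in range(n_psu)], m)
        rounds = np.tile(["2011"] * (m // 2) + ["2018"] * (m // 2), n_psu)
        p_base = 0.30 + 0.15 * (rounds == "2018")
        y = (rng.random(n_psu * m) < p_base).astype(float)
        d, p = adjusted_wald(y, rounds, np.ones(n_psu * m), psu, ("2011", "2018"))
        assert d == pytest.approx(15.0, abs=5.0)
        assert p < 0.01

    def test_single_psu_variance_undefined(self):
        with pytest.raises(EstimationError):
            adjusted_wald(np.array([1.0, 0.0]), np.array(["2011", "2018"]),
                          np.ones(2), np.array(["A", "A"]), ("2011", "2018"))


class TestSummaries:
    def _df(self, values, weights, flags=None):
        n = len(values)
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)], "round": "2011",
            "age_years": 30.0, "sex": "male", "sampling_weight": weights,
            "x": values, "flag": flags if flags is not None else [False] * n,
        })

    def test_equal_weights(self, analysis):
        out = summarize_cells(self._df([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]),
                              SurveyDesign(), analysis.bands, ["x"])
        assert out["x_mean"].iloc[0] == pytest.approx(2.0)
        assert out["x_median"].iloc[0] == pytest.approx(2.0)

    def test_weighted_mean_by_hand(self, analysis):
        out = summarize_cells(self._df([1.0, 2.0, 3.0], [1.0, 1.0, 2.0]),
                              SurveyDesign(), analysis.bands, ["x"])
        assert out["x_mean"].iloc[0] == pytest.approx(2.25)

    def test_weighted_prevalence(self, analysis):
        out = summarize_cells(
            self._df([1.0, 1.0], [3.0, 1.0], flags=[True, False]),
            SurveyDesign(), analysis.bands, [], flag_cols=["flag"])
        assert out["flag_prev"].iloc[0] == pytest.approx(75.0)

    def test_order_and_weight_scale_invariance(self, analysis):
        rng = np.random.default_rng(9)
        v = rng.lognormal(7.0, 0.4, 50)
        w = rng.uniform(0.5, 2.0, 50)
        a = summarize_cells(self._df(v, w), SurveyDesign(), analysis.bands, ["x"])
        perm = rng.permutation(50)
        b = summarize_cells(self._df(v[perm], 10.0 * w[perm]), SurveyDesign(),
                            analysis.bands, ["x"])
        for col in ("x_mean", "x_sd", "x_median"):
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0], rel=1e-9)


def test_weighted_median_walk():
    assert weighted_median(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 5.0])) == 3.0
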