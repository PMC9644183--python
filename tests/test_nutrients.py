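"""Nutrient engine: totals, energy shares, item matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dietiq import nutrients
from dietiq.errors import UndefinedSharesError, UnresolvedItemError
from dietiq.nutrients import (PersonDayIntake, compute_intake, compute_intakes,
                              energy_shares, match_items)


def _mini_fct():
    return pd.DataFrame({
        "item_name": ["rice", "fish", "oil"],
        "energy_kcal_100g": [130.0, 110.0, 900.0],
        "protein_g_100g": [2.7, 10.0, 0.0],
        "fat_g_100g": [0.3, 4.0, 100.0],
        "carb_g_100g": [28.0, 0.0, 0.0],
        "edible_coeff": [1.0, 0.8, 1.0],
        "food_group_mddw": ["grains_roots_tubers", "meat_poultry_fish", "other"],
        "food_group_who7": ["grains_roots_tubers", "flesh_foods", "other"],
    })


class TestComputeIntake:
    def test_unit_case(self):
        out = compute_intake([("rice", 100.0)], _mini_fct())
        assert out.energy_kcal == pytest.approx(130.0)

    def test_edible_coefficient_applied(self):
        # 200 g as-purchased * 0.8 edible / 100 * 10 g protein = 16 g
        out = compute_intake([("fish", 200.0)], _mini_fct())
        assert out.protein_g == pytest.approx(16.0)

    def test_empty_record_list_flagged(self):
        out = compute_intake([], _mini_fct())
        assert out.energy_kcal == 0.0
        assert out.items_consumed == set()
        assert out.zero_energy

    def test_unresolved_item_never_dropped(self):
        with pytest.raises(UnresolvedItemError, match="dragonfruit"):
            compute_intake([("dragonfruit", 50.0)], _mini_fct())

    @given(
        qty=hst.lists(hst.floats(1.0, 500.0), min_size=1, max_size=6),
        factor=hst.floats(1.5, 4.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_linear_in_quantities_and_order_free(self, qty, factor):
        fct = _mini_fct()
        names = [fct["item_name"][i % 3] for i in range(len(qty))]
        base = compute_intake(list(zip(names, qty)), fct)
        doubled = compute_intake([(n, q * factor) for n, q in zip(names, qty)], fct)
        shuffled = compute_intake(list(zip(names, qty))[::-1], fct)
        for attr in ("energy_kcal", "protein_g", "fat_g", "carb_g"):
            assert getattr(doubled, attr) == pytest.approx(
                factor * getattr(base, attr), rel=1e-12)
            assert getattr(shuffled, attr) == pytest.approx(
                getattr(base, attr), rel=1e-12)


class TestEnergyShares:
    def test_hand_worked_profile(self):
        intake = PersonDayIntake("p", "r", energy_kcal=1580.0, protein_g=50.0,
                                 fat_g=20.0, carb_g=300.0)
        energy_shares(intake)
        assert intake.pct_energy_protein == pytest.approx(12.66, abs=0.005)
        assert intake.pct_energy_fat == pytest.approx(11.39, abs=0.005)
        assert intake.pct_energy_carb == pytest.approx(75.95, abs=0.005)

    def test_all_carb_diet(self):
        intake = PersonDayIntake("p", "r", energy_kcal=400.0, carb_g=100.0)
        energy_shares(intake)
        assert intake.pct_energy_carb == pytest.approx(100.0)

    def test_zero_energy_undefined(self):
        with pytest.raises(UndefinedSharesError):
            energy_shares(PersonDayIntake("p", "r"))

    def test_shares_sum_to_100_on_consistent_fct(self, small_bundle):
        rec = small_bundle["food_records"]
        out = compute_intakes(rec.assign(item_key=rec["item_name"]),
                              small_bundle["fct"])
        total = (out["pct_energy_protein"] + out["pct_energy_fat"]
                 + out["pct_energy_carb"])
        np.testing.assert_allclose(total, 100.0, rtol=1e-9)


class TestMatchItems:
    def test_normalisation_and_sources(self):
        fct = _mini_fct()
        fallback = _mini_fct().assign(item_name=["quinoa", "sardine", "ghee"])
        rec = pd.DataFrame({
            "person_id": ["a"] * 3, "round": ["2011"] * 3,
            "item_name": [" Rice ", "GHEE", "durian"],
            "quantity_g": [100.0, 10.0, 50.0],
        })
        out, report = match_items(rec, fct, fallback)
        assert list(out["match_source"]) == ["primary", "fallback", "unmatched"]
        assert out["item_key"].tolist()[:2] == ["rice", "ghee"]
        assert report.unmatched == ["durian"]
        assert report.n_primary == 1 and report.n_fallback == 1

    def test_strict_mode_raises(self):
        rec = pd.DataFrame({"person_id": ["a"], "round": ["2011"],
                            "item_name": ["durian"], "quantity_g": [1.0]})
        with pytest.raises(UnresolvedItemError, match="durian"):
            match_items(rec, _mini_fct(), strict=True)


def test_vectorised_totals_match_scalar_route(small_bundle):
    """compute_intakes agrees with the per-person scalar computation."""
    rec = small_bundle["food_records"]
    fct = small_bundle["fct"]
    table = compute_intakes(rec.assign(item_key=rec["item_name"]), fct)
    sample = table.sample(10, random_state=0)
    for _, row in sample.iterrows():
        sub = rec[(rec["person_id"] == row["person_id"])
                  & (rec["round"] == row["round"])]
        scalar = compute_intake(
            list(zip(sub["item_name"], sub["quantity_g"])), fct)
        assert scalar.energy_kcal == pytest.approx(row["energy_kcal"], rel=1e-9)
        assert scalar.protein_g == pytest.approx(row["protein_g"], rel=1e-9)
        assert scalar.items_consumed == set(row["items_consumed"].split(";"))
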