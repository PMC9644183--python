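"""Food records -> daily energy and macronutrient intakes.

Each recorded quantity is as-purchased grams; the edible fraction of the item
is applied before the per-100-g densities of the composition table, so

    nutrient = sum over records of  quantity_g * edible_coeff / 100 * density.

Energy shares are computed with Atwater factors (4/9/4 kcal/g by default)
against the *stated* table energy, not re-normalised to 100: the adequacy
rules compare shares of actual energy intake, and a composition row whose
energy disagrees with its Atwater sum is a data problem flagged upstream, not
something to paper over here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import UndefinedSharesError, UnresolvedItemError

ATWATER = {"protein": 4.0, "fat": 9.0, "carb": 4.0}


@dataclass
class PersonDayIntake:
    """One person's one-day totals."""

    person_id: str
    round: str
    energy_kcal: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    carb_g: float = 0.0
    pct_energy_protein: float = float("nan")
    pct_energy_fat: float = float("nan")
    pct_energy_carb: float = float("nan")
    items_consumed: set = field(default_factory=set)
    zero_energy: bool = False


@dataclass
class MatchReport:
    """Outcome of matching recorded item names against composition tables."""

    n_primary: int
    n_fallback: int
    unmatched: list[str]

    @property
    def ok(self) -> bool:
        return not self.unmatched


def _norm(name: str) -> str:
    return str(name).strip().casefold()


def match_items(
    records: pd.DataFrame,
    fct: pd.DataFrame,
    fallback_fct: pd.DataFrame | None = None,
    *,
    strict: bool = False,
) -> tuple[pd.DataFrame, MatchReport]:
    """Resolve record item names against a primary, then a fallback, table.

    Matching is exact after trimming and case-folding. Returns the records
    with an added ``item_key`` (canonical name) and ``match_source`` column
    (``primary`` / ``fallback`` / ``unmatched``), plus a report. In strict
    mode any unmatched name raises :class:`UnresolvedItemError`.
    """
    primary = {_norm(n): n for n in fct["item_name"]}
    fallback = (
        {_norm(n): n for n in fallback_fct["item_name"]}
        if fallback_fct is not None else {}
    )
    out = records.copy()
    norm = out["item_name"].map(_norm)
    out["item_key"] = norm.map(primary)
    out["match_source"] = np.where(out["item_key"].notna(), "primary", "unmatched")
    if fallback:
        fb = norm.map(fallback)
        use_fb = out["item_key"].isna() & fb.notna()
        out.loc[use_fb, "item_key"] = fb[use_fb]
        out.loc[use_fb, "match_source"] = "fallback"
    unmatched = sorted(out.loc[out["item_key"].isna(), "item_name"].unique())
    report = MatchReport(
        n_primary=int((out["match_source"] == "primary").sum()),
        n_fallback=int((out["match_source"] == "fallback").sum()),
        unmatched=unmatched,
    )
    if strict and unmatched:
        raise UnresolvedItemError(
            f"unmatched food item(s): {unmatched}", unmatched
        )
    return out, report


def compute_intake(
    records: Iterable[Mapping | tuple[str, float]],
    fct: pd.DataFrame,
    *,
    atwater: Mapping[str, float] | None = None,
) -> PersonDayIntake:
    """Totals for a single person-day from an iterable of records.

    Records may be ``(item_name, quantity_g)`` pairs or mappings with those
    keys (plus optional ``person_id``/``round``). Unknown items raise
    :class:`UnresolvedItemError` — never silently dropped. An empty record
    list yields an all-zero intake flagged ``zero_energy``.
    """
    fct_idx = fct.set_index(fct["item_name"].map(_norm))
    intake = PersonDayIntake(person_id="", round="")
    n = 0
    for rec in records:
        if isinstance(rec, Mapping):
            name, qty = rec["item_name"], float(rec["quantity_g"])
            intake.person_id = str(rec.get("person_id", intake.person_id))
            intake.round = str(rec.get("round", intake.round))
        else:
            name, qty = rec[0], float(rec[1])
        key = _norm(name)
        if key not in fct_idx.index:
            raise UnresolvedItemError(f"unresolved food item {name!r}", [name])
        row = fct_idx.loc[key]
        scale = qty * float(row["edible_coeff"]) / 100.0
        intake.energy_kcal += scale * float(row["energy_kcal_100g"])
        intake.protein_g += scale * float(row["protein_g_100g"])
        intake.fat_g += scale * float(row["fat_g_100g"])
        intake.carb_g += scale * float(row["carb_g_100g"])
        if qty > 0:
            intake.items_consumed.add(str(row["item_name"]))
        n += 1
    intake.zero_energy = intake.energy_kcal <= 0
    if not intake.zero_energy:
        energy_shares(intake, atwater=atwater)
    return intake


def energy_shares(intake: PersonDayIntake, *,
                  atwater: Mapping[str, float] | None = None) -> PersonDayIntake:
    """Fill ``pct_energy_*`` in place: ``100 * factor * grams / energy``."""
    at = atwater or ATWATER
    if intake.energy_kcal <= 0:
        raise UndefinedSharesError(
            f"energy shares undefined for zero-energy person-day "
            f"({intake.person_id!r}, {intake.round!r})"
        )
    e = intake.energy_kcal
    intake.pct_energy_protein = 100.0 * at["protein"] * intake.protein_g / e
    intake.pct_energy_fat = 100.0 * at["fat"] * intake.fat_g / e
    intake.pct_energy_carb = 100.0 * at["carb"] * intake.carb_g / e
    return intake


def compute_intakes(
    records: pd.DataFrame,
    fct: pd.DataFrame,
    *,
    atwater: Mapping[str, float] | None = None,
    intake_consistency_band: tuple[float, float] = (0.90, 1.10),
) -> pd.DataFrame:
    """Vectorised person-day totals for a full food-record table.

    *records* must already be matched (``item_key`` column from
    :func:`match_items`; plain ``item_name`` is accepted and matched
    strictly). Returns one row per (person_id, round) with grams, energy,
    shares (NaN for zero-energy days), a semicolon-joined ``items_consumed``
    list, and flags ``zero_energy`` / ``atwater_flag`` (energy outside the
    consistency band of the Atwater sum).
    """
    at = atwater or ATWATER
    if "item_key" not in records.columns:
        records, report = match_items(records, fct, strict=True)
    merged = records.merge(
        fct, left_on="item_key", right_on="item_name",
        suffixes=("", "_fct"), how="left", validate="many_to_one",
    )
    scale = merged["quantity_g"] * merged["edible_coeff"] / 100.0
    merged["_energy"] = scale * merged["energy_kcal_100g"]
    merged["_protein"] = scale * merged["protein_g_100g"]
    merged["_fat"] = scale * merged["fat_g_100g"]
    merged["_carb"] = scale * merged["carb_g_100g"]
    merged["_item"] = np.where(merged["quantity_g"] > 0, merged["item_key"], None)

    grp = merged.groupby(["person_id", "round"], sort=True)
    out = grp[["_energy", "_protein", "_fat", "_carb"]].sum()
    out.columns = ["energy_kcal", "protein_g", "fat_g", "carb_g"]
    out["items_consumed"] = grp["_item"].agg(
        lambda s: ";".join(sorted(set(x for x in s if x is not None)))
    )
    out = out.reset_index()

    e = out["energy_kcal"].to_numpy()
    out["zero_energy"] = e <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_energy_protein"] = np.where(
            e > 0, 100.0 * at["protein"] * out["protein_g"] / e, np.nan)
        out["pct_energy_fat"] = np.where(
            e > 0, 100.0 * at["fat"] * out["fat_g"] / e, np.nan)
        out["pct_energy_carb"] = np.where(
            e > 0, 100.0 * at["carb"] * out["carb_g"] / e, np.nan)
        atwater_sum = (at["protein"] * out["protein_g"]
                       + at["fat"] * out["fat_g"]
                       + at["carb"] * out["carb_g"])
        ratio = np.where(e > 0, atwater_sum / e, 1.0)
    lo, hi = intake_consistency_band
    out["atwater_flag"] = (ratio < lo) | (ratio > hi)
    return out
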