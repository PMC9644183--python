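"""Energy requirements and adequacy classification.

The estimated energy requirement (EER) of a person is the product of a
weight-based basal metabolic rate prediction (BMR, kcal/d) and a physical
activity level multiplier (PAL): ``EER = BMR x PAL``. Energy intake below a
configurable fraction of the EER (default 85%) is classified *insufficient*.

Macronutrient adequacy compares the percentage of energy supplied by protein,
fat and carbohydrate against the Acceptable Macronutrient Distribution Ranges
(AMDR) for the person's age: below the range is *insufficient*, above it
*excessive*, and values equal to either bound count as *within*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SEXES
from .errors import CoefficientGapError, ConfigError, OutOfScopeError, ValidationError

INSUFFICIENT = "insufficient"
WITHIN = "within"
EXCESSIVE = "excessive"


@dataclass(frozen=True)
class BMRRow:
    sex: str
    age_lower: float
    age_upper: float  # exclusive; inf allowed
    slope: float  # kcal/kg/d
    intercept: float  # kcal/d


class BMRCoefficientTable:
    """Piecewise-linear BMR prediction coefficients by sex and age.

    Rows must partition each sex's age range without overlap; validated at
    construction time.
    """

    def __init__(self, rows: Sequence[BMRRow]):
        self.rows = list(rows)
        for sex in SEXES:
            sub = sorted(
                (r for r in self.rows if r.sex == sex), key=lambda r: r.age_lower
            )
            for a, b in zip(sub, sub[1:]):
                if b.age_lower < a.age_upper - 1e-12:
                    raise ConfigError(
                        f"overlapping BMR rows for sex={sex}: "
                        f"[{a.age_lower},{a.age_upper}) and "
                        f"[{b.age_lower},{b.age_upper})"
                    )

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "BMRCoefficientTable":
        return cls([BMRRow(**{str(k): v for k, v in r.items()}) for r in records])

    def lookup(self, sex: str, age_years: float) -> BMRRow:
        for row in self.rows:
            if row.sex == sex and row.age_lower <= age_years < row.age_upper:
                return row
        raise CoefficientGapError(
            f"no BMR coefficients cover sex={sex!r}, age={age_years} y"
        )


@dataclass(frozen=True)
class AMDRRow:
    age_lower: float
    age_upper: float  # exclusive; inf allowed
    fat: tuple[float, float]
    carb: tuple[float, float]
    protein: tuple[float, float]


class AMDRTable:
    """Acceptable macronutrient distribution ranges (% of energy) by age."""

    def __init__(self, rows: Sequence[AMDRRow]):
        self.rows = sorted(rows, key=lambda r: r.age_lower)
        for row in self.rows:
            for name in ("fat", "carb", "protein"):
                lo, hi = getattr(row, name)
                if not lo < hi:
                    raise ConfigError(f"AMDR {name} bounds not increasing: {lo}, {hi}")
        for a, b in zip(self.rows, self.rows[1:]):
            if not math.isclose(a.age_upper, b.age_lower):
                raise ConfigError("AMDR rows do not partition the age range")

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "AMDRTable":
        rows = [
            AMDRRow(
                age_lower=float(r["age_lower"]),
                age_upper=float(r["age_upper"]),
                fat=tuple(r["fat"]),
                carb=tuple(r["carb"]),
                protein=tuple(r["protein"]),
            )
            for r in records
        ]
        return cls(rows)

    def lookup(self, age_years: float) -> AMDRRow:
        if age_years < self.rows[0].age_lower:
            raise OutOfScopeError(
                f"age {age_years} y below AMDR table lower bound "
                f"({self.rows[0].age_lower} y)"
            )
        for row in self.rows:
            if row.age_lower <= age_years < row.age_upper:
                return row
        raise CoefficientGapError(f"no AMDR row covers age {age_years} y")


def bmr(sex: str, age_years: float, body_weight_kg: float,
        coeffs: BMRCoefficientTable) -> float:
    """Predicted basal metabolic rate, kcal/d, from body weight."""
    if body_weight_kg <= 0:
        raise ValidationError(f"body weight must be positive, got {body_weight_kg}")
    row = coeffs.lookup(sex, age_years)
    return row.slope * body_weight_kg + row.intercept


def eer(bmr_kcal: float, pal: float) -> float:
    """Estimated energy requirement: BMR x PAL (both positive)."""
    if bmr_kcal <= 0 or pal <= 0:
        raise ValidationError("BMR and PAL must both be positive")
    return bmr_kcal * pal


def classify_energy(intake_kcal: float, eer_kcal: float,
                    threshold: float = 0.85) -> bool:
    """True iff intake is strictly below ``threshold x EER``."""
    if eer_kcal <= 0:
        raise ValidationError("EER must be positive")
    return intake_kcal < threshold * eer_kcal


def classify_macros(shares: tuple[float, float, float], age_years: float,
                    table: AMDRTable) -> tuple[str, str, str]:
    """Classify (protein%, fat%, carb%) energy shares against the AMDR.

    Returns a status triple in the same (protein, fat, carb) order; bounds
    are inclusive as *within*.
    """
    row = table.lookup(age_years)

    def status(share: float, bounds: tuple[float, float]) -> str:
        lo, hi = bounds
        if share < lo:
            return INSUFFICIENT
        if share > hi:
            return EXCESSIVE
        return WITHIN

    p, f, c = shares
    return (status(p, row.protein), status(f, row.fat), status(c, row.carb))


def classify_adequacy(
    intakes: pd.DataFrame,
    persons: pd.DataFrame,
    *,
    bmr_coeffs: BMRCoefficientTable,
    amdr: AMDRTable,
    pal_map: Mapping[str, str],
    pal_levels: Mapping[str, float],
    energy_threshold: float = 0.85,
) -> pd.DataFrame:
    """Vectorised adequacy classification for a person-day intake table.

    *intakes* must carry person_id, round, energy_kcal and the three
    ``pct_energy_*`` columns; *persons* supplies age, sex, body weight and
    occupation class. Returns one row per person-day with ``eer_kcal``,
    ``energy_insufficient`` and the three macronutrient statuses.
    """
    cols = ["person_id", "round", "age_years", "sex", "body_weight_kg",
            "occupation_class"]
    df = intakes.merge(persons[cols], on=["person_id", "round"],
                       how="left", validate="many_to_one")
    missing = df["age_years"].isna()
    if missing.any():
        raise ValidationError(
            f"{int(missing.sum())} intake rows have no matching person record"
        )

    bmr_vals = np.empty(len(df))
    for i, (sex, age, w) in enumerate(
        zip(df["sex"], df["age_years"], df["body_weight_kg"])
    ):
        bmr_vals[i] = bmr(sex, float(age), float(w), bmr_coeffs)

    unknown = set(df["occupation_class"]) - set(pal_map)
    if unknown:
        raise ConfigError(f"occupation classes missing from PAL map: {sorted(unknown)}")
    pal_vals = df["occupation_class"].map(
        {occ: pal_levels[lvl] for occ, lvl in pal_map.items()}
    ).to_numpy(dtype=float)

    eer_vals = bmr_vals * pal_vals
    out = df[["person_id", "round"]].copy()
    out["eer_kcal"] = eer_vals
    out["energy_insufficient"] = (
        df["energy_kcal"].to_numpy() < energy_threshold * eer_vals
    )
    statuses = [
        classify_macros((p, f, c), float(age), amdr)
        for p, f, c, age in zip(
            df["pct_energy_protein"], df["pct_energy_fat"],
            df["pct_energy_carb"], df["age_years"],
        )
    ]
    out["protein_status"] = [s[0] for s in statuses]
    out["fat_status"] = [s[1] for s in statuses]
    out["carb_status"] = [s[2] for s in statuses]
    return out
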