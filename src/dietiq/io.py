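"""CSV schemas, readers, writers and validators.

Four flat tables drive the pipeline (UTF-8, comma-separated, period decimal
mark, header row):

``households.csv``
    household_id, psu_id, stratum_id, round, sampling_weight,
    monthly_expenditure, n_members
``persons.csv``
    person_id, household_id, round, age_years, sex, body_weight_kg,
    occupation_class
``food_records.csv``
    person_id, round, item_name, quantity_g
``fct.csv``
    item_name, energy_kcal_100g, protein_g_100g, fat_g_100g, carb_g_100g,
    edible_coeff, food_group_mddw, food_group_who7

Validation is strict by default (first violation raises); in lenient mode
offending rows are dropped and returned as row-level diagnostics. Missing
columns always raise :class:`SchemaError`; dangling join keys always raise
:class:`ReferentialError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MDDW_GROUPS, MIN_ANALYSIS_AGE, NOT_COUNTED, SEXES, WHO7_GROUPS
from .errors import ReferentialError, SchemaError, ValidationError

SCHEMAS: dict[str, dict[str, type]] = {
    "households": {
        "household_id": str,
        "psu_id": str,
        "stratum_id": str,
        "round": str,
        "sampling_weight": float,
        "monthly_expenditure": float,
        "n_members": int,
    },
    "persons": {
        "person_id": str,
        "household_id": str,
        "round": str,
        "age_years": float,
        "sex": str,
        "body_weight_kg": float,
        "occupation_class": str,
    },
    "food_records": {
        "person_id": str,
        "round": str,
        "item_name": str,
        "quantity_g": float,
    },
    "fct": {
        "item_name": str,
        "energy_kcal_100g": float,
        "protein_g_100g": float,
        "fat_g_100g": float,
        "carb_g_100g": float,
        "edible_coeff": float,
        "food_group_mddw": str,
        "food_group_who7": str,
    },
}


@dataclass(frozen=True)
class Diagnostic:
    """One rejected row (lenient mode) or consistency flag."""

    table: str
    row: int  # positional index in the input file
    column: str
    message: str


def _check_columns(df: pd.DataFrame, kind: str) -> None:
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind}: missing column(s) {missing}")


def _coerce(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    out = df.copy()
    for col, typ in SCHEMAS[kind].items():
        if typ is str:
            out[col] = out[col].astype(str)
        elif typ is int:
            out[col] = pd.to_numeric(out[col]).astype(int)
        else:
            out[col] = pd.to_numeric(out[col]).astype(float)
    return out[list(SCHEMAS[kind])]


def _row_rules(kind: str, df: pd.DataFrame) -> list[tuple[pd.Series, str, str]]:
    """(bad-row mask, column, message) triples for each invariant."""
    if kind == "households":
        return [
            (df["sampling_weight"] <= 0, "sampling_weight", "must be > 0"),
            (df["monthly_expenditure"] <= 0, "monthly_expenditure", "must be > 0"),
            (df["n_members"] < 1, "n_members", "must be >= 1"),
        ]
    if kind == "persons":
        return [
            (df["age_years"] < MIN_ANALYSIS_AGE, "age_years",
             f"below analysis minimum ({MIN_ANALYSIS_AGE} y)"),
            (~df["sex"].isin(SEXES), "sex", f"must be one of {SEXES}"),
            (df["body_weight_kg"] <= 0, "body_weight_kg", "must be > 0"),
        ]
    if kind == "food_records":
        return [
            (df["quantity_g"] < 0, "quantity_g", "must be >= 0"),
            (df["item_name"].str.strip() == "", "item_name", "must be nonempty"),
        ]
    if kind == "fct":
        valid_mddw = set(MDDW_GROUPS) | {NOT_COUNTED}
        valid_who7 = set(WHO7_GROUPS) | {NOT_COUNTED}
        nutrient_cols = ["energy_kcal_100g", "protein_g_100g", "fat_g_100g",
                         "carb_g_100g"]
        neg = pd.Series(False, index=df.index)
        for c in nutrient_cols:
            neg |= df[c] < 0
        return [
            ((df["edible_coeff"] <= 0) | (df["edible_coeff"] > 1),
             "edible_coeff", "must be in (0, 1]"),
            (neg, "energy_kcal_100g", "nutrient densities must be >= 0"),
            (~df["food_group_mddw"].isin(valid_mddw), "food_group_mddw",
             "unknown MDD-W group"),
            (~df["food_group_who7"].isin(valid_who7), "food_group_who7",
             "unknown WHO-7 group"),
        ]
    raise SchemaError(f"unknown table kind {kind!r}")


def validate_table(
    df: pd.DataFrame, kind: str, *, lenient: bool = False,
    atwater: Mapping[str, float] | None = None,
    fct_consistency_band: tuple[float, float] = (0.70, 1.30),
) -> tuple[pd.DataFrame, list[Diagnostic]]:
    """Type-coerce and validate one table; see module docstring for modes.

    For the FCT, rows whose stated energy falls outside
    ``fct_consistency_band`` times the Atwater sum are *flagged* (diagnostic +
    ``atwater_flag`` column), not rejected: the discrepancy band is a data-
    quality signal, not a hard invariant.
    """
    _check_columns(df, kind)
    out = _coerce(df, kind)
    diags: list[Diagnostic] = []
    bad_any = pd.Series(False, index=out.index)
    for mask, col, msg in _row_rules(kind, out):
        if mask.any():
            if not lenient:
                first = int(mask.idxmax())
                raise ValidationError(f"{kind} row {first}, {col}: {msg}")
            for i in out.index[mask & ~bad_any]:
                diags.append(Diagnostic(kind, int(i), col, msg))
            bad_any |= mask
    out = out[~bad_any].reset_index(drop=True)

    if kind == "fct":
        at = atwater or {"protein": 4.0, "fat": 9.0, "carb": 4.0}
        atwater_sum = (
            at["protein"] * out["protein_g_100g"]
            + at["fat"] * out["fat_g_100g"]
            + at["carb"] * out["carb_g_100g"]
        )
        lo, hi = fct_consistency_band
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = atwater_sum / out["energy_kcal_100g"]
        flagged = (ratio < lo) | (ratio > hi)
        flagged &= out["energy_kcal_100g"] > 0
        out["atwater_flag"] = flagged.fillna(False)
        for i in out.index[out["atwater_flag"]]:
            diags.append(
                Diagnostic(kind, int(i), "energy_kcal_100g",
                           f"Atwater sum is {100 * ratio[i]:.0f}% of stated energy "
                           f"(band {100 * lo:.0f}-{100 * hi:.0f}%)")
            )
    return out, diags


def check_references(tables: Mapping[str, pd.DataFrame]) -> None:
    """Verify join keys across the bundle; raise listing offending ids."""
    if "persons" in tables and "households" in tables:
        known = set(zip(tables["households"]["household_id"],
                        tables["households"]["round"]))
        keys = set(zip(tables["persons"]["household_id"], tables["persons"]["round"]))
        orphans = sorted(k[0] for k in keys - known)
        if orphans:
            raise ReferentialError(
                f"persons reference unknown household_id(s): {orphans}", orphans
            )
    if "food_records" in tables and "persons" in tables:
        known = set(zip(tables["persons"]["person_id"], tables["persons"]["round"]))
        keys = set(zip(tables["food_records"]["person_id"],
                       tables["food_records"]["round"]))
        orphans = sorted(k[0] for k in keys - known)
        if orphans:
            raise ReferentialError(
                f"food records reference unknown person_id(s): {orphans}", orphans
            )


def read_tables(
    paths: Mapping[str, str | Path], *, lenient: bool = False,
    atwater: Mapping[str, float] | None = None,
    fct_consistency_band: tuple[float, float] = (0.70, 1.30),
) -> tuple[dict[str, pd.DataFrame], list[Diagnostic]]:
    """Read and validate a bundle of CSVs keyed by table kind.

    Referential integrity (persons -> households, food records -> persons) is
    checked across whichever tables are present.
    """
    tables: dict[str, pd.DataFrame] = {}
    diags: list[Diagnostic] = []
    for kind, path in paths.items():
        if kind not in SCHEMAS:
            raise SchemaError(f"unknown table kind {kind!r}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        clean, d = validate_table(
            df, kind, lenient=lenient, atwater=atwater,
            fct_consistency_band=fct_consistency_band,
        )
        tables[kind] = clean
        diags.extend(d)
    check_references(tables)
    return tables, diags


def write_tables(tables: Mapping[str, pd.DataFrame],
                 out_dir: str | Path) -> dict[str, Path]:
    """Write each table as ``<kind>.csv`` under *out_dir*; returns the paths.

    Floats are written with full round-trip precision so a write/read cycle
    is value-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for kind, df in tables.items():
        path = out_dir / f"{kind}.csv"
        df.to_csv(path, index=False)
        written[kind] = path
    return written


def load_fct(path: str | Path, **kwargs) -> pd.DataFrame:
    """Convenience reader for a standalone food-composition table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    clean, _ = validate_table(df, "fct", **kwargs)
    return clean
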