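"""Food-group assignment and minimum dietary diversity.

Two schemes, switched on age: children below the switch age (default 10 y)
are scored on the WHO 7-group child indicator (minimum diversity = at least
4 groups in 24 h); everyone else on the 10-group MDD-W scheme (at least 5
groups). Both thresholds are inclusive. Items mapped to the non-counted
category (oils, sugar, condiments) never contribute a group.

No diversity indicator has been validated for children aged 2-10 y; applying
the WHO child scheme there is a deliberate, documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import MDDW_GROUPS, NOT_COUNTED, SurveyDesign, WHO7_GROUPS

MDDW10 = "MDDW10"
WHO7 = "WHO7"


@dataclass(frozen=True)
class DiversityResult:
    person_id: str
    round: str
    scheme: str
    groups_consumed: frozenset
    n_groups: int
    meets_mdd: bool


def score_diversity(
    items_consumed: Iterable[str],
    fct: pd.DataFrame,
    age_years: float,
    *,
    person_id: str = "",
    round_label: str = "",
    scheme_switch_age: float = 10.0,
    who7_threshold: int = 4,
    mddw_threshold: int = 5,
) -> DiversityResult:
    """Score one person-day's consumed item set under the age-appropriate scheme."""
    use_who7 = age_years < scheme_switch_age
    col = "food_group_who7" if use_who7 else "food_group_mddw"
    group_of = dict(zip(fct["item_name"], fct[col]))
    groups = {group_of[i] for i in items_consumed} - {NOT_COUNTED}
    threshold = who7_threshold if use_who7 else mddw_threshold
    return DiversityResult(
        person_id=person_id,
        round=round_label,
        scheme=WHO7 if use_who7 else MDDW10,
        groups_consumed=frozenset(groups),
        n_groups=len(groups),
        meets_mdd=len(groups) >= threshold,
    )


def score_diversity_table(
    intakes: pd.DataFrame,
    fct: pd.DataFrame,
    persons: pd.DataFrame,
    *,
    scheme_switch_age: float = 10.0,
    who7_threshold: int = 4,
    mddw_threshold: int = 5,
) -> pd.DataFrame:
    """Vectorised diversity scores for a person-day intake table.

    Consumes the semicolon-joined ``items_consumed`` column produced by
    :func:`dietiq.nutrients.compute_intakes`. Returns one row per person-day
    with scheme, group membership indicator columns (``grp_<name>``),
    ``n_groups`` and ``meets_mdd``.
    """
    df = intakes[["person_id", "round", "items_consumed"]].merge(
        persons[["person_id", "round", "age_years"]],
        on=["person_id", "round"], validate="one_to_one",
    )
    long = df.assign(item=df["items_consumed"].str.split(";")).explode("item")
    long = long[long["item"].notna() & (long["item"] != "")]
    long = long.merge(
        fct[["item_name", "food_group_mddw", "food_group_who7"]],
        left_on="item", right_on="item_name", how="left",
    )
    use_who7 = long["age_years"] < scheme_switch_age
    long["group"] = np.where(
        use_who7, long["food_group_who7"], long["food_group_mddw"]
    )
    long = long[long["group"] != NOT_COUNTED]

    # indicator per (person-day, group), then pivot wide
    ind = (
        long.groupby(["person_id", "round", "group"]).size().gt(0).astype(int)
        .rename("v").reset_index()
        .pivot_table(index=["person_id", "round"], columns="group", values="v",
                     fill_value=0)
    )
    all_groups = list(dict.fromkeys(MDDW_GROUPS + WHO7_GROUPS))
    for g in all_groups:
        if g not in ind.columns:
            ind[g] = 0
    ind = ind[all_groups]
    ind.columns = [f"grp_{g}" for g in ind.columns]

    out = df[["person_id", "round", "age_years"]].merge(
        ind.reset_index(), on=["person_id", "round"], how="left"
    ).fillna(0)
    child = out["age_years"] < scheme_switch_age
    out["scheme"] = np.where(child, WHO7, MDDW10)

    who7_cols = [f"grp_{g}" for g in WHO7_GROUPS]
    mddw_cols = [f"grp_{g}" for g in MDDW_GROUPS]
    n_who7 = out[who7_cols].sum(axis=1)
    n_mddw = out[mddw_cols].sum(axis=1)
    out["n_groups"] = np.where(child, n_who7, n_mddw).astype(int)
    out["meets_mdd"] = np.where(
        child, n_who7 >= who7_threshold, n_mddw >= mddw_threshold
    )
    return out.drop(columns=["age_years"])


def group_prevalence(
    diversity: pd.DataFrame,
    persons: pd.DataFrame,
    design: SurveyDesign,
    bands,
) -> pd.DataFrame:
    """Weighted food-group and minimum-diversity prevalences per cell.

    Cells are band x sex x round. Persons must carry the design weight
    column (attach household weights upstream). Empty cells are simply
    absent from the output (missing-cell marker), never reported as zero.
    Prevalences are percentages.
    """
    from .core import assign_age_band

    cols = ["person_id", "round", "age_years", "sex", design.weight_col]
    df = diversity.merge(persons[cols], on=["person_id", "round"],
                         validate="one_to_one")
    df["band"] = [assign_age_band(a, bands).label for a in df["age_years"]]
    w = df[design.weight_col]

    grp_cols = [c for c in df.columns if c.startswith("grp_")]
    rows = []
    for (band, sex, rnd), cell in df.groupby(["band", "sex", "round"], sort=True):
        cw = cell[design.weight_col].to_numpy()
        total = cw.sum()
        rec = {"band": band, "sex": sex, "round": rnd, "n": len(cell)}
        for c in grp_cols:
            rec[c.removeprefix("grp_")] = 100.0 * float(
                (cell[c].to_numpy() * cw).sum() / total
            )
        rec["minimum_dietary_diversity"] = 100.0 * float(
            (cell["meets_mdd"].to_numpy() * cw).sum() / total
        )
        rows.append(rec)
    return pd.DataFrame(rows)
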