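"""Expenditure gradients: quintiles, fractional ranks, CIX and SII.

Persons are ranked by household per-capita expenditure, pooled across both
survey rounds, with person-level survey weights. Two rank-based summary
indices quantify how an outcome concentrates along that ranking:

Concentration index (CIX)
    ``CIX = 100 * (2 / mu) * cov_w(y, r)`` where ``r`` is the weighted
    midpoint fractional rank and ``mu`` the weighted mean of the outcome.
    Negative values: the outcome is concentrated among the poor. For a binary
    outcome the index lives in [-100, 100].

Slope index of inequality (SII)
    The slope of a weighted regression of the outcome (scaled 0/100) on the
    fractional rank: the model-implied gap, in percentage points, between the
    very bottom (r=0) and very top (r=1) of the expenditure distribution.

Standard errors respect the survey design: the SII uses PSU-cluster-robust
covariance; the CIX uses a leave-one-PSU-out jackknife (ranks held fixed
across replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import SurveyDesign
from .errors import DegenerateDistributionError, EstimationError, UndefinedIndexError

QUINTILES = ("Q1", "Q2", "Q3", "Q4", "Q5")


@dataclass(frozen=True)
class IndexEstimate:
    value: float
    se: float


def per_capita_expenditure(households: pd.DataFrame) -> pd.Series:
    """Household monthly expenditure divided by member count."""
    return households["monthly_expenditure"] / households["n_members"]


def fractional_rank(
    values: np.ndarray,
    weights: np.ndarray,
    tiebreak: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted midpoint ranks in (0, 1), in input order.

    After a stable ascending sort (*tiebreak* orders equal values, e.g.
    (household_id, person_id)), ``r_i = (W_<i + w_i / 2) / W`` with ``W_<i``
    the weight mass strictly before record *i*.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise DegenerateDistributionError("weights must be positive")
    if tiebreak is None:
        order = np.argsort(values, kind="stable")
    else:
        order = np.lexsort((np.asarray(tiebreak), values))
    w_sorted = weights[order]
    cum = np.cumsum(w_sorted)
    ranks_sorted = (cum - w_sorted / 2.0) / cum[-1]
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return ranks


def assign_quintiles(
    values: np.ndarray,
    weights: np.ndarray,
    tiebreak: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled weighted quintiles plus fractional ranks.

    Each record lands in the fifth of the cumulative weight distribution that
    contains its own weight midpoint, i.e. ``Q = 1 + floor(5 r)``. Returns
    (labels in Q1..Q5, fractional ranks). Q1 is the poorest fifth.
    """
    values = np.asarray(values, dtype=float)
    if np.all(values == values[0]):
        raise DegenerateDistributionError(
            "all expenditure values identical: quintiles undefined"
        )
    r = fractional_rank(values, weights, tiebreak)
    idx = np.minimum((5 * r).astype(int), 4)
    return np.array(QUINTILES)[idx], r


def concentration_index(
    y: np.ndarray,
    ranks: np.ndarray,
    weights: np.ndarray,
    psu: np.ndarray | None = None,
) -> IndexEstimate:
    """Weighted concentration index on the -100..100 scale.

    SE by delete-one-PSU jackknife when *psu* is given (NaN with fewer than
    2 PSUs or no psu vector).
    """
    y = np.asarray(y, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    w = np.asarray(weights, dtype=float)

    def _cix(yv, rv, wv):
        mu = np.average(yv, weights=wv)
        if mu == 0:
            raise UndefinedIndexError("outcome mean is zero: CIX undefined")
        rbar = np.average(rv, weights=wv)
        cov = np.average(yv * (rv - rbar), weights=wv)
        return 100.0 * 2.0 * cov / mu

    est = _cix(y, ranks, w)
    se = float("nan")
    if psu is not None:
        groups = np.unique(psu)
        if len(groups) >= 2:
            reps = []
            for g in groups:
                keep = psu != g
                try:
                    reps.append(_cix(y[keep], ranks[keep], w[keep]))
                except UndefinedIndexError:
                    reps.append(est)
            reps = np.asarray(reps)
            g_n = len(groups)
            se = float(np.sqrt((g_n - 1) / g_n * np.sum((reps - reps.mean()) ** 2)))
    return IndexEstimate(float(est), se)


def slope_index(
    y: np.ndarray,
    ranks: np.ndarray,
    weights: np.ndarray,
    psu: np.ndarray | None = None,
) -> IndexEstimate:
    """SII from individual-level data: weighted LS of y (0/100) on rank.

    Cluster-robust (PSU) standard error when *psu* is given, else HC1.
    """
    y = np.asarray(y, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if len(y) < 3:
        raise EstimationError("need at least 3 observations for the SII")
    if np.all(ranks == ranks[0]):
        raise EstimationError("all ranks equal: slope undefined")
    X = sm.add_constant(ranks)
    model = sm.WLS(y, X, weights=np.asarray(weights, dtype=float))
    if psu is not None and len(np.unique(psu)) >= 2:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(psu)})
    else:
        fit = model.fit(cov_type="HC1")
    return IndexEstimate(float(fit.params[1]), float(fit.bse[1]))


def slope_index_from_quintiles(
    prevalences: np.ndarray,
    quintile_weights: np.ndarray | None = None,
    mid_ranks: np.ndarray | None = None,
) -> float:
    """Cross-check variant: SII from 5 quintile prevalences (already in %).

    Fits the same weighted LS on the quintile midpoint ranks (0.1 .. 0.9 for
    equal-mass quintiles) and returns the slope.
    """
    p = np.asarray(prevalences, dtype=float)
    r = (np.asarray(mid_ranks, dtype=float) if mid_ranks is not None
         else np.arange(0.1, 1.0, 0.2))
    w = (np.asarray(quintile_weights, dtype=float) if quintile_weights is not None
         else np.ones_like(p))
    rbar = np.average(r, weights=w)
    pbar = np.average(p, weights=w)
    cov = np.average((r - rbar) * (p - pbar), weights=w)
    var = np.average((r - rbar) ** 2, weights=w)
    return float(cov / var)


def attach_expenditure_ranks(
    persons: pd.DataFrame,
    households: pd.DataFrame,
    design: SurveyDesign,
) -> pd.DataFrame:
    """Join per-capita expenditure onto persons and rank the pooled sample.

    Returns persons plus ``per_capita_expenditure``, ``fractional_rank``,
    ``quintile`` and the design columns (weight, PSU, stratum) inherited from
    the household. Quintiles and ranks are computed on the pooled two-round
    person-level distribution, so a fixed living standard can shift quintile
    when the other round is richer.
    """
    hh = households.copy()
    hh["per_capita_expenditure"] = per_capita_expenditure(hh)
    cols = ["household_id", "round", "per_capita_expenditure",
            design.weight_col, design.psu_col, design.stratum_col]
    df = persons.merge(hh[cols], on=["household_id", "round"],
                       how="left", validate="many_to_one")
    if df["per_capita_expenditure"].isna().any():
        raise EstimationError("persons without household expenditure present")
    tiebreak = np.lexsort(
        (df["person_id"].to_numpy(), df["household_id"].to_numpy())
    ).argsort()  # stable (household_id, person_id) order as an integer key
    quint, ranks = assign_quintiles(
        df["per_capita_expenditure"].to_numpy(),
        df[design.weight_col].to_numpy(),
        tiebreak,
    )
    df["quintile"] = quint
    df["fractional_rank"] = ranks
    return df


def equity_results(
    outcomes: pd.DataFrame,
    ranked_persons: pd.DataFrame,
    design: SurveyDesign,
    bands,
    outcome_cols: list[str],
) -> pd.DataFrame:
    """Full inequity table: one row per outcome x band x sex x round.

    *outcomes* holds boolean columns named in *outcome_cols* keyed by
    (person_id, round); *ranked_persons* comes from
    :func:`attach_expenditure_ranks`. Each row carries the five weighted
    quintile prevalences (percent), the SII (pp) and CIX with standard
    errors. Cells with fewer than 2 PSUs or an all-zero/all-one outcome get
    NaN indices rather than being dropped.
    """
    from .core import assign_age_band

    keep = ["person_id", "round", "age_years", "sex", "quintile",
            "fractional_rank", design.weight_col, design.psu_col]
    df = outcomes.merge(ranked_persons[keep], on=["person_id", "round"],
                        validate="one_to_one")
    df["band"] = [assign_age_band(a, bands).label for a in df["age_years"]]

    rows = []
    for (band, sex, rnd), cell in df.groupby(["band", "sex", "round"], sort=True):
        w = cell[design.weight_col].to_numpy()
        r = cell["fractional_rank"].to_numpy()
        psu = cell[design.psu_col].to_numpy()
        for col in outcome_cols:
            y = cell[col].to_numpy(dtype=float)
            rec = {"outcome": col, "band": band, "sex": sex, "round": rnd,
                   "n": len(cell)}
            for q in QUINTILES:
                m = (cell["quintile"] == q).to_numpy()
                rec[f"prev_{q}"] = (
                    100.0 * float(np.average(y[m], weights=w[m])) if m.any()
                    else float("nan")
                )
            try:
                sii = slope_index(100.0 * y, r, w, psu)
                rec["sii_pp"], rec["sii_se"] = sii.value, sii.se
            except EstimationError:
                rec["sii_pp"] = rec["sii_se"] = float("nan")
            try:
                cix = concentration_index(y, r, w, psu)
                rec["cix"], rec["cix_se"] = cix.value, cix.se
            except UndefinedIndexError:
                rec["cix"] = rec["cix_se"] = float("nan")
            rows.append(rec)
    return pd.DataFrame(rows)
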