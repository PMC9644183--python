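"""Round-to-round change statistics.

Continuous intakes are compared on the log scale: a weighted linear model of
log(intake) on a round indicator with PSU-cluster-robust variance. The
exponentiated coefficient is the ratio of weighted geometric means between
rounds (an algebraic identity when the model holds only the round term), the
natural summary for right-skewed intake distributions.

Categorical outcomes use a design-based adjusted Wald test: weighted
difference in proportions, variance from a delete-one-PSU jackknife, referred
to F(1, #PSU - #strata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .core import SurveyDesign
from .errors import EstimationError, UndefinedChangeError


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (published-table convention).

    The value is first snapped to 12 significant digits so that a quantity
    that is exactly representable in decimal (e.g. 9.8/80 = 12.25%) rounds on
    its decimal value, not on its nearest binary float.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(f"{x:.12g}").quantize(Decimal(1).scaleb(-ndigits),
                                      rounding=ROUND_HALF_UP)
    return float(q)


def pct_change(v0: float, v1: float) -> float:
    """Percent change ``100 * (v1 - v0) / v0``; undefined for v0 = 0.

    Table rendering rounds the result half-away-from-zero to one decimal
    (:func:`round_half_away`).
    """
    if v0 == 0:
        raise UndefinedChangeError("percent change from a zero baseline")
    return 100.0 * (v1 - v0) / v0


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TrendResult:
    measure: str
    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    n_excluded_zero: int = 0


def intake_ratio(
    values: np.ndarray,
    rounds: np.ndarray,
    weights: np.ndarray,
    psu: np.ndarray,
    round_labels: tuple[str, str],
    *,
    measure: str = "intake",
) -> TrendResult:
    """Geometric-mean ratio (round 2 / round 1) with cluster-robust 95% CI.

    Zero or negative intakes are excluded from the log model and counted in
    ``n_excluded_zero``.
    """
    values = np.asarray(values, dtype=float)
    rounds = np.asarray(rounds)
    keep = values > 0
    n_excl = int((~keep).sum())
    values, rounds = values[keep], rounds[keep]
    weights = np.asarray(weights, dtype=float)[keep]
    psu = np.asarray(psu)[keep]
    for lab in round_labels:
        if not np.any(rounds == lab):
            raise EstimationError(f"round {lab!r} has no positive intakes")
    if len(values) < 3:
        raise EstimationError("too few positive intakes to fit the log model")
    ind = (rounds == round_labels[1]).astype(float)
    X = sm.add_constant(ind)
    model = sm.WLS(np.log(values), X, weights=weights)
    if len(np.unique(psu)) >= 2:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": psu})
    else:
        fit = model.fit(cov_type="HC1")
    b, se = float(fit.params[1]), float(fit.bse[1])
    return TrendResult(
        measure=measure,
        ratio=math.exp(b),
        ci_low=math.exp(b - 1.96 * se),
        ci_high=math.exp(b + 1.96 * se),
        p_value=float(fit.pvalues[1]),
        test="glm_log",
        n_excluded_zero=n_excl,
    )


def adjusted_wald(
    y: np.ndarray,
    rounds: np.ndarray,
    weights: np.ndarray,
    psu: np.ndarray,
    round_labels: tuple[str, str],
    *,
    strata: np.ndarray | None = None,
) -> tuple[float, float]:
    """Design-based difference in weighted proportions between rounds.

    Returns ``(difference in pp, p-value)``. The variance of the difference
    comes from a delete-one-PSU jackknife (a dropped PSU leaves both rounds
    simultaneously, so within-PSU correlation across rounds is respected);
    the test statistic is referred to F(1, #PSU - #strata).
    """
    y = np.asarray(y, dtype=float)
    rounds = np.asarray(rounds)
    w = np.asarray(weights, dtype=float)
    psu = np.asarray(psu)
    groups = np.unique(psu)
    n_strata = len(np.unique(strata)) if strata is not None else 1
    if len(groups) < 2:
        raise EstimationError("at least 2 PSUs required for a design-based variance")
    df_denom = len(groups) - n_strata
    if df_denom < 1:
        raise EstimationError("non-positive design degrees of freedom")

    m0, m1 = rounds == round_labels[0], rounds == round_labels[1]
    if not m0.any() or not m1.any():
        raise EstimationError("both rounds must be nonempty")

    def _diff(mask_keep):
        a, b = m0 & mask_keep, m1 & mask_keep
        return (np.average(y[b], weights=w[b])
                - np.average(y[a], weights=w[a]))

    # vectorised jackknife via per-PSU sums
    tab = pd.DataFrame({"psu": psu, "r1": m1, "wy": w * y, "w": w})
    sums = tab.groupby(["psu", "r1"]).sum().unstack(fill_value=0.0)
    wy0 = sums[("wy", False)].reindex(groups, fill_value=0.0).to_numpy()
    wy1 = sums[("wy", True)].reindex(groups, fill_value=0.0).to_numpy()
    w0 = sums[("w", False)].reindex(groups, fill_value=0.0).to_numpy()
    w1 = sums[("w", True)].reindex(groups, fill_value=0.0).to_numpy()
    W0, W1, WY0, WY1 = w0.sum(), w1.sum(), wy0.sum(), wy1.sum()
    d_full = 100.0 * (WY1 / W1 - WY0 / W0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p0_g = (WY0 - wy0) / (W0 - w0)
        p1_g = (WY1 - wy1) / (W1 - w1)
    p0_g = np.where(np.isfinite(p0_g), p0_g, WY0 / W0)
    p1_g = np.where(np.isfinite(p1_g), p1_g, WY1 / W1)
    reps = 100.0 * (p1_g - p0_g)
    g_n = len(groups)
    var = (g_n - 1) / g_n * np.sum((reps - reps.mean()) ** 2)
    if var <= 0:
        return float(d_full), 1.0
    f_stat = d_full ** 2 / var
    p_val = float(st.f.sf(f_stat, 1, df_denom))
    return float(d_full), p_val


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def summarize_cells(
    df: pd.DataFrame,
    design: SurveyDesign,
    bands,
    value_cols: list[str],
    flag_cols: list[str] | None = None,
    *,
    shapiro_max_n: int = 500,
) -> pd.DataFrame:
    """Weighted mean/SD/median per band x sex x round for *value_cols* and
    weighted prevalence (percent) for boolean *flag_cols*.

    A Shapiro-Wilk normality p-value is recorded per continuous cell
    (informational; computed on an unweighted subsample capped at
    *shapiro_max_n*). Empty cells are absent from the output.
    """
    from .core import assign_age_band

    df = df.copy()
    df["band"] = [assign_age_band(a, bands).label for a in df["age_years"]]
    rows = []
    for (band, sex, rnd), cell in df.groupby(["band", "sex", "round"], sort=True):
        w = cell[design.weight_col].to_numpy(dtype=float)
        rec = {"band": band, "sex": sex, "round": rnd, "n": len(cell)}
        for col in value_cols:
            v = cell[col].to_numpy(dtype=float)
            mean = np.average(v, weights=w)
            var = np.average((v - mean) ** 2, weights=w)
            rec[f"{col}_mean"] = float(mean)
            rec[f"{col}_sd"] = float(np.sqrt(var))
            rec[f"{col}_median"] = weighted_median(v, w)
            sample = v if len(v) <= shapiro_max_n else v[:shapiro_max_n]
            if len(sample) >= 3 and np.ptp(sample) > 0:
                rec[f"{col}_shapiro_p"] = float(st.shapiro(sample).pvalue)
            else:
                rec[f"{col}_shapiro_p"] = float("nan")
        for col in flag_cols or []:
            v = cell[col].to_numpy(dtype=float)
            rec[f"{col}_prev"] = 100.0 * float(np.average(v, weights=w))
        rows.append(rec)
    return pd.DataFrame(rows)
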