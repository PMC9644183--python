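# dietiq

Individual-level dietary analysis for two-round household surveys of the
rural-Bangladesh type: 24-h recall food records are converted into nutrient
intakes, dietary-diversity indicators, energy and macronutrient adequacy
classifications, and expenditure-gradient inequity measures with
design-based round-to-round trend statistics. A synthetic-data module
reproduces the statistical structure of such a survey (two rounds, PSU
clustering, sampling weights, expenditure-linked gradients) so the entire
pipeline runs and is testable with no external data.

## Who this is for

Nutrition epidemiologists and survey statisticians working with
person-level food consumption data from complex household surveys — the
kind where a household roster carries sampling weights and cluster (PSU)
ids, a member roster carries age/sex/body weight/occupation, and a food
table records grams of each raw ingredient consumed per person per day,
matched against a food composition table (FCT).

## What it computes

**Nutrient engine.** For person *i* with records *(q, item)*,

    nutrient_i = Σ q · edible_coeff(item) / 100 · density_100g(item)

with energy shares from Atwater factors (4/9/4 kcal/g):
`%E_fat = 100 · 9 · F / E`, etc.

**Dietary diversity.** Items map to the 10 MDD-W food groups (ages ≥ 10;
minimum diversity = ≥ 5 groups in 24 h) or to the WHO 7-group child scheme
(ages 2–<10; ≥ 4 groups). Oils/sugar never count.

**Adequacy.** EER = BMR × PAL, with BMR from FAO/WHO/UNU (2004) weight-based
equations by sex and age and PAL ∈ {1.4, 1.7, 2.0} from occupation class.
Energy intake `< 0.85 · EER` is *insufficient*. Macronutrient energy shares
are classified against the Institute of Medicine AMDRs (adults: fat 20–35%,
carbohydrate 45–65%, protein 10–35%; with the 1–3 y and 4–18 y ranges for
children); below the range is insufficient, above it excessive, the bounds
inclusive as within.

**Inequity.** Persons are ranked by household per-capita expenditure pooled
over both rounds (weighted midpoint fractional ranks r ∈ (0,1), quintiles
Q1 = poorest … Q5 = richest). Two rank-based indices on the −100..100 scale:

- Concentration index: `CIX = 100 · (2/μ) · cov_w(y, r)` (negative =
  concentrated among the poor); SE by leave-one-PSU-out jackknife.
- Slope index of inequality: slope of the survey-weighted regression of the
  outcome (0/100) on r — the model-implied gap in percentage points between
  the extremes of the expenditure distribution; PSU-cluster-robust SE.

**Trends.** Continuous intakes: weighted regression of log intake on a round
indicator with PSU-cluster-robust variance; the exponentiated coefficient is
the ratio of weighted geometric means with a 95% CI. Categorical outcomes:
design-based adjusted Wald test (weighted difference in proportions,
delete-one-PSU jackknife variance, F(1, #PSU − #strata) reference).
Published-style change columns use `100 · (v1 − v0)/v0` rounded
half-away-from-zero to one decimal.

## Worked example

```python
import numpy as np
from dietiq import nutrients, equity, trends
from dietiq.core import SurveyDesign
from dietiq.synthetic import GeneratorConfig, generate

bundle = generate(GeneratorConfig(n_psu=60, households_per_psu=20, seed=11))
rec = bundle["food_records"]
intakes = nutrients.compute_intakes(rec.assign(item_key=rec["item_name"]),
                                    bundle["fct"])
ranked = equity.attach_expenditure_ranks(bundle["persons"],
                                         bundle["households"], SurveyDesign())
df = intakes.merge(ranked[["person_id", "round", "sampling_weight",
                           "psu_id", "fractional_rank"]],
                   on=["person_id", "round"])

res = trends.intake_ratio(df["energy_kcal"].to_numpy(), df["round"].to_numpy(),
                          df["sampling_weight"].to_numpy(),
                          df["psu_id"].to_numpy(), ("2011", "2018"))
print(f"energy ratio 2018/2011: {res.ratio:.3f} "
      f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")

low_fat = (df["pct_energy_fat"] < 20).to_numpy(float)
sii = equity.slope_index(100 * low_fat, df["fractional_rank"].to_numpy(),
                         df["sampling_weight"].to_numpy(),
                         df["psu_id"].to_numpy())
cix = equity.concentration_index(low_fat, df["fractional_rank"].to_numpy(),
                                 df["sampling_weight"].to_numpy())
print(f"fat share <20% of energy: SII = {sii.value:.1f} pp "
      f"(SE {sii.se:.1f}), CIX = {cix.value:.2f}")
```

prints

```
energy ratio 2018/2011: 0.929 (95% CI 0.915-0.942)
fat share <20% of energy: SII = -20.7 pp (SE 1.2), CIX = -4.06
```

The generator programmed a 0.92 multiplicative round effect on energy, and
the estimated geometric-mean ratio recovers it within its confidence
interval. The negative SII and CIX say that low fat intake is concentrated
among poorer households: the regression-implied gap between the very bottom
and very top of the expenditure distribution is about 21 percentage points.

The same steps run end to end from the command line:

```sh
dietiq simulate --out data --seed 7          # four CSVs + truth.json
dietiq run --out results --seed 7            # all analysis tables
```

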