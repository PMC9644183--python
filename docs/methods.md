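# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, the parameters that matter, and what the synthetic
data do and do not establish.

## Population and units of analysis

The analysis population is household members aged ≥ 2 years; younger
children are excluded by the readers (a 24-h recall of breastmilk and
complementary feeding needs instruments this pipeline does not model). The
unit of observation is the *person-day*: one person's total consumption over
the recalled 24 hours in one survey round. Rounds are treated as repeated
cross-sections; no panel linkage of individuals across rounds is attempted.

Reporting age bands default to six groups — 2–<5, 5–<10, 10–18, 19–40,
41–60, ≥61 years — lower-inclusive/upper-exclusive on real-valued ages, and
are fully configurable (`age_bands` in the YAML config).

## Nutrient engine

Each record is grams *as purchased*; the item's edible coefficient (fraction
of purchased weight that is edible) is applied before the per-100-g
densities of the food composition table (FCT). Totals are linear in
quantities and invariant to record order.

Energy shares use Atwater factors 4/9/4 kcal/g (configurable) and are taken
against the FCT's *stated* energy, not re-normalised to sum to 100. The
adequacy rules are defined on shares of actual energy intake; re-normalising
would silently repair FCT rows whose stated energy disagrees with their
Atwater sum. Instead two consistency bands flag suspect data:

- FCT rows whose stated energy is outside 70–130% of 4P + 9F + 4C;
- person-days whose computed energy is outside 90–110% of the Atwater sum
  of their computed macronutrients.

Item matching is exact after trimming and case-folding, first against the
primary FCT and then an optional fallback table (the pattern used when a
national FCT is supplemented by an external database). Unmatched items are
never silently dropped: strict mode aborts naming them; lenient mode reports
them and flags the affected person-days.

Cooking-method nutrient retention factors are not modelled: no public
retention table exists for this survey context, and the records analysed are
raw-ingredient weights. This is a documented limitation — fat-soluble
vitamin losses do not matter here (micronutrients are out of scope), and
macronutrient retention corrections are second-order relative to recall
error.

## Dietary diversity

Two fixed schemes, switched on age (default switch at 10 years):

- **WHO 7-group child indicator**, ages 2–<10: grains/roots/tubers,
  legumes/nuts, dairy, flesh foods, eggs, vitamin-A-rich fruits and
  vegetables, other fruits and vegetables. Minimum diversity: ≥ 4 groups.
- **MDD-W 10-group scheme**, ages ≥ 10: grains/roots/tubers, pulses,
  nuts/seeds, dairy, meat/poultry/fish, eggs, dark green leafy vegetables,
  other vitamin-A-rich fruits/vegetables, other vegetables, other fruits.
  Minimum diversity: ≥ 5 groups.

Both thresholds are inclusive. Items outside every counted group (oils,
sugar, condiments) carry a `NOT_COUNTED` category and never contribute; the
canonical guidelines likewise exclude them from the count. No diversity
indicator has been validated for children aged 2–10; applying the WHO child
scheme there is a convention, flagged as such.

## Energy requirement and adequacy

`EER = BMR × PAL`. BMR comes from the FAO/WHO/UNU (2004) weight-based
prediction equations by sex and age class (e.g. men 18–30:
`15.057·W + 692.2` kcal/d); the coefficient table is configuration data, so
an alternative equation set (e.g. a re-fit Schofield) drops in without code
changes. PAL is 1.4 (light), 1.7 (moderate) or 2.0 (heavy), assigned from
the member's reported occupation class through a configurable map; the
default maps non-working classes (students, homemakers, retired/none) to
light activity — an explicit assumption, since occupation codebooks differ
by survey. Children's growth-energy increments are represented only to the
extent the coefficient table encodes them.

Energy intake strictly below 85% of EER is *insufficient* (the threshold is
a config key). Macronutrient shares are classified against the IOM AMDRs:
ages 1–3: fat 30–40%, carbohydrate 45–65%, protein 5–20%; ages 4–18:
25–35 / 45–65 / 10–30; adults: 20–35 / 45–65 / 10–35. Classification uses
the person's exact age (so the 2–<5 reporting band mixes the 1–3 and 4–18
AMDR rows by design); results are aggregated into reporting bands
afterwards. Values equal to a bound count as *within* ("below or above the
range" defines the risk states).

## Expenditure ranking and inequity indices

Household monthly expenditure divided by member count proxies living
standards. Persons inherit their household's per-capita expenditure and
sampling weight; ranking is at person level over the *pooled* two-round
distribution, so quintile cutpoints are common to both rounds and
round-specific index values are comparable. Fractional ranks are weighted
midpoint ranks, `r_i = (W_<i + w_i/2)/W`, after a stable sort with
(household, person) tie-breaking; a record's quintile is the fifth of the
cumulative weight distribution containing its own weight midpoint
(`Q = 1 + floor(5r)`).

The concentration index is `100 · (2/μ) · cov_w(y, r)`; for a binary
outcome with prevalence μ its attainable range is ±100(1−μ), a bound the
property tests exercise. Its standard error is a leave-one-PSU-out jackknife
with fractional ranks held fixed across replicates (re-ranking each
replicate is the documented alternative; at survey sizes the difference is
far below the jackknife's own Monte-Carlo noise, and fixed ranks keep the
estimator linear in cell data). The SII is estimated on individual-level
data by weighted least squares of the 0/100 outcome on rank with
PSU-cluster-robust covariance; a quintile-aggregate variant
(`slope_index_from_quintiles`) exists for cross-checks, and the two agree
exactly when each quintile is summarised at its midpoint rank with equal
mass.

Sign convention throughout: negative = concentrated among the poor.

## Trend statistics

Intake distributions are right-skewed, so round comparisons for continuous
intakes are made on the log scale: weighted least squares of log intake on a
round indicator with PSU-cluster-robust variance. With only the round term
in the model the exponentiated coefficient *is* the ratio of weighted
geometric means (an algebraic identity, tested), and the 95% CI is
`exp(b ± 1.96·SE)`. Zero-intake person-days are excluded from the log model
and counted in the output — they carry real information (a fasting or
unrecorded day) that a log model cannot absorb.

Categorical outcomes use a design-based adjusted Wald test: the weighted
difference in proportions, with variance from a delete-one-PSU jackknife in
which a dropped PSU leaves both rounds simultaneously (PSUs are shared
across rounds, so this respects within-PSU correlation over time), referred
to F(1, #PSU − #strata). Its type-I error is verified by simulation against
the null outcome-level generator (500 replicates at 100 PSUs; acceptance
band 3–7% at the 5% level).

Cell summaries report weighted mean, SD and median per band × sex × round,
plus an informational Shapiro–Wilk normality p-value computed on an
unweighted subsample capped at 500 (the statistic's null distribution is
unreliable at larger n, and the check only motivates the log-scale
analysis). Published-style change columns round half away from zero to one
decimal, with the value first snapped to 12 significant digits so decimal
quantities like 12.25% round on their decimal value.

## Synthetic-data generator

The generator emulates the survey's statistical skeleton: ~275 PSUs × 20
households per round across 7 strata, lognormal household sampling weights,
lognormal per-capita expenditure (round-specific location, so mean
expenditure grows ~16% between rounds), six age bands with a realistic
rural age pyramid, sex-balanced membership, piecewise-linear growth curves
for body weight, and occupation-based PAL mixes by age/sex.

Person-day intakes are built in two layers. A *base diet* adopts each food
group by a Bernoulli draw whose logit shifts with standardised log
expenditure (richer households more often consume eggs, dairy, fruit, meat,
pulses) and with a round-2 shift (diversity improves between rounds);
adopted groups contribute one item with lognormal grams. Three *adjuster*
staples — rice (carbohydrate), soybean oil (fat), dried fish (protein) —
then receive solved grams from a 3×3 linear system so that the person-day
macronutrient totals hit their targets exactly; when the base diet alone
would overshoot (small children, low-noise draws), it is shrunk by a factor
in (0,1] to keep all solved grams nonnegative (≈7% of person-days at
default settings). The bundled 30-item FCT is exactly Atwater-consistent,
so generated energy equals 4P + 9F + 4C by construction.

Targets: energy is `baseline(band, sex) × round effect × exp(β_E z) ×
lognormal noise` with β_E = 0.06 per SD of log expenditure, noise CV 0.25,
and a round-2 multiplier of 0.92 — an *exact* multiplicative shift, which is
what makes the geometric-mean-ratio recovery checks sharp. The fat energy
share is `baseline × round effect (1.30 in round 2) + 0.015·z + N(0,
0.065)`, clipped to [0.06, 0.40]; the protein share is baseline + N(0,
0.008) clipped to [0.085, 0.16]; carbohydrate takes the remainder. Baseline
energies and shares per band × sex encode a carbohydrate-dominant profile
(~76–79% of energy from carbohydrate, ~10% protein, 11–14% fat). The
fat-share spread of 6.5 pp was chosen so that the implied adequacy
prevalences sit in the realistic regime (fat insufficiency ~90–96%,
carbohydrate excess ~90–99%) rather than saturating at 100%, and it, the
gradients and the round effects are the fixed study conditions of the test
suite, not tuning knobs.

What the generator does **not** emulate: real Bangladeshi food frequencies
beyond group coverage (dried fish appears daily as the protein adjuster, so
flesh-food prevalence is ~100% rather than ~78%), guests, leftovers and
food away from home (it emits net individual consumption directly),
attrition or household splits, seasonality, and any real codebook of
occupations or items. Consequently, a passing suite shows that the
*estimators* recover known structure from data with the right statistical
shape — clustering, weights, gradients, skew — not that the generator's
food patterns match any real population.

Two reduced generators support calibration studies at the outcome level:
`simulate_null_prevalence` (a null two-round clustered binary survey with
shared and round-specific PSU effects on the prevalence logit, used for the
Wald type-I check — running the full food-record machinery 500 times would
add runtime but no information, since the test consumes only round, PSU,
weight and outcome) and `rank_linear_outcome` (prevalence linear in
fractional rank, whose population SII is the programmed slope).

## Numerical choices and degenerate inputs

- Quantile/rank ties: stable sort with (household, person) keys; all-equal
  expenditure raises rather than fabricating quintiles.
- CIX with zero outcome mean, SII with < 3 observations or constant ranks,
  Wald with < 2 PSUs: explicit errors, reported as missing cells by the
  pipeline rather than zeros.
- Empty band × sex × round cells are absent from outputs, never imputed.
- Simulation sizes: recovery checks run at 200 PSUs × 20 households
  (~30,000 person-days), the scale at which ±2 Monte-Carlo SEs separate the
  programmed effects from zero; the Wald calibration uses 500 replicates at
  100 PSUs.
- Determinism: all randomness flows from a single integer seed through
  `numpy.random.default_rng`; a rerun with the same configuration is
  byte-identical, and every pipeline output carries a seed + config-hash
  sidecar.

## Known limitations

- Macronutrients only; micronutrient adequacy needs FCT columns and
  reference intakes this pipeline does not carry.
- BMR equations and PAL assignment are both configurable approximations;
  misclassification of occupation directly shifts energy-insufficiency
  prevalence (the 85% threshold sits on the steep part of the intake
  distribution).
- The CIX jackknife holds ranks fixed; with very few PSUs (< ~30) its SE is
  noisy and the linearised alternative would be preferable.
- Pregnancy/lactation energy adjustments, adult-male-equivalent scaling and
  intra-household allocation modelling are out of scope.
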