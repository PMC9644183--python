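"""Synthetic two-round household survey generator.

Emulates the statistical structure the analysis assumes — two survey rounds,
PSU-clustered two-stage sampling with weights, households with lognormal
per-capita expenditure, members spanning six age bands, expenditure-linked
gradients in food-group adoption and in the fat energy share, and
multiplicative round effects on intake levels — so every downstream stage can
be tested against known ground truth with no external data.

Construction of a person-day diet proceeds in two layers:

1. *Base diet*: each food group is adopted by a Bernoulli draw whose logit
   shifts with standardised log expenditure (and a round effect); an adopted
   group contributes one item with lognormal grams.
2. *Adjusters*: grams of three staple adjuster foods — rice (carbohydrate),
   soybean oil (fat), dried fish (protein) — are solved from a 3x3 linear
   system so the person-day macronutrient totals, and hence energy, hit the
   configured targets exactly. When the base diet alone would overshoot a
   target, it is shrunk (factor in (0,1]) to keep all solved grams
   nonnegative.

Because the bundled composition table is Atwater-consistent, person-day
energy equals the Atwater sum of the generated macronutrients by
construction, and the configured round effect on energy is an exact
multiplicative shift of every individual's intake distribution — the property
the recovery checks downstream rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import ConfigError

# ---------------------------------------------------------------------------
# bundled food-composition fixture

# name, protein, fat, carb (g/100 g edible), edible_coeff, mddw group, who7 group
_FCT_ITEMS = [
    ("rice", 6.8, 0.5, 78.0, 1.00, "grains_roots_tubers", "grains_roots_tubers"),
    ("wheat flour", 11.0, 1.7, 72.0, 1.00, "grains_roots_tubers", "grains_roots_tubers"),
    ("potato", 2.0, 0.1, 19.0, 0.85, "grains_roots_tubers", "grains_roots_tubers"),
    ("lentil", 25.0, 1.1, 59.0, 1.00, "pulses", "legumes_nuts"),
    ("chickpea", 19.0, 6.0, 61.0, 1.00, "pulses", "legumes_nuts"),
    ("mung bean", 24.0, 1.2, 60.0, 1.00, "pulses", "legumes_nuts"),
    ("peanut", 26.0, 49.0, 16.0, 0.70, "nuts_seeds", "legumes_nuts"),
    ("sesame", 18.0, 50.0, 23.0, 1.00, "nuts_seeds", "legumes_nuts"),
    ("milk", 3.3, 3.6, 4.7, 1.00, "dairy", "dairy"),
    ("yogurt", 3.5, 3.3, 5.0, 1.00, "dairy", "dairy"),
    ("chicken", 19.0, 9.0, 0.0, 0.70, "meat_poultry_fish", "flesh_foods"),
    ("beef", 18.0, 15.0, 0.0, 0.80, "meat_poultry_fish", "flesh_foods"),
    ("rohu fish", 17.0, 5.0, 0.0, 0.60, "meat_poultry_fish", "flesh_foods"),
    ("hilsa fish", 19.0, 19.0, 0.0, 0.65, "meat_poultry_fish", "flesh_foods"),
    ("dried fish", 55.0, 5.0, 0.0, 0.80, "meat_poultry_fish", "flesh_foods"),
    ("egg", 12.5, 10.0, 1.0, 0.88, "eggs", "eggs"),
    ("spinach", 2.9, 0.4, 3.6, 0.80, "dark_green_leafy_vegetables",
     "vitamin_a_fruits_vegetables"),
    ("amaranth leaves", 3.5, 0.3, 4.0, 0.75, "dark_green_leafy_vegetables",
     "vitamin_a_fruits_vegetables"),
    ("carrot", 0.9, 0.2, 9.6, 0.90, "other_vitamin_a_fruits_vegetables",
     "vitamin_a_fruits_vegetables"),
    ("ripe mango", 0.8, 0.4, 15.0, 0.69, "other_vitamin_a_fruits_vegetables",
     "vitamin_a_fruits_vegetables"),
    ("pumpkin", 1.0, 0.1, 6.5, 0.80, "other_vitamin_a_fruits_vegetables",
     "vitamin_a_fruits_vegetables"),
    ("eggplant", 1.0, 0.2, 5.7, 0.90, "other_vegetables", "other_fruits_vegetables"),
    ("cabbage", 1.3, 0.1, 5.8, 0.80, "other_vegetables", "other_fruits_vegetables"),
    ("okra", 1.9, 0.2, 7.0, 0.85, "other_vegetables", "other_fruits_vegetables"),
    ("onion", 1.1, 0.1, 9.0, 0.90, "other_vegetables", "other_fruits_vegetables"),
    ("banana", 1.1, 0.3, 22.8, 0.64, "other_fruits", "other_fruits_vegetables"),
    ("guava", 2.6, 1.0, 14.0, 0.85, "other_fruits", "other_fruits_vegetables"),
    ("soybean oil", 0.0, 100.0, 0.0, 1.00, "other", "other"),
    ("mustard oil", 0.0, 100.0, 0.0, 1.00, "other", "other"),
    ("sugar", 0.0, 0.0, 100.0, 1.00, "other", "other"),
]

#: The three adjuster foods whose grams are solved, not drawn.
ADJUSTERS = ("rice", "soybean oil", "dried fish")


def make_fixture_fct() -> pd.DataFrame:
    """Bundled food-composition table; energy is the exact Atwater sum."""
    rows = []
    for name, p, f, c, ec, mddw, who7 in _FCT_ITEMS:
        rows.append({
            "item_name": name,
            "energy_kcal_100g": 4.0 * p + 9.0 * f + 4.0 * c,
            "protein_g_100g": p,
            "fat_g_100g": f,
            "carb_g_100g": c,
            "edible_coeff": ec,
            "food_group_mddw": mddw,
            "food_group_who7": who7,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration

_BANDS = ("2 to <5 y", "5 to <10 y", "10-18 y", "19-40 y", "41-60 y", ">=61 y")
_BAND_EDGES = {
    "2 to <5 y": (2.0, 5.0), "5 to <10 y": (5.0, 10.0), "10-18 y": (10.0, 19.0),
    "19-40 y": (19.0, 41.0), "41-60 y": (41.0, 61.0), ">=61 y": (61.0, 90.0),
}


def _default_age_sex_structure() -> dict:
    # Survey-like age composition among members >= 2 y; sexes balanced.
    by_band = {"2 to <5 y": 0.068, "5 to <10 y": 0.134, "10-18 y": 0.204,
               "19-40 y": 0.351, "41-60 y": 0.178, ">=61 y": 0.065}
    return {(b, s): p / 2.0 for b, p in by_band.items() for s in ("male", "female")}


def _default_baseline_intake() -> dict:
    # (energy kcal/d, protein energy share, fat energy share); carbohydrate
    # takes the remainder — a carb-dominant rural South Asian profile.
    return {
        ("2 to <5 y", "male"): (1014.0, 0.104, 0.139),
        ("5 to <10 y", "male"): (1514.0, 0.102, 0.117),
        ("10-18 y", "male"): (2216.0, 0.101, 0.108),
        ("19-40 y", "male"): (2780.0, 0.102, 0.112),
        ("41-60 y", "male"): (2685.0, 0.102, 0.111),
        (">=61 y", "male"): (2352.0, 0.105, 0.118),
        ("2 to <5 y", "female"): (977.0, 0.103, 0.130),
        ("5 to <10 y", "female"): (1494.0, 0.101, 0.111),
        ("10-18 y", "female"): (2048.0, 0.102, 0.110),
        ("19-40 y", "female"): (2364.0, 0.101, 0.108),
        ("41-60 y", "female"): (2254.0, 0.103, 0.112),
        (">=61 y", "female"): (1943.0, 0.104, 0.114),
    }


def _default_occupation_pal_probs() -> dict:
    return {
        "child": {"light": 1.0, "moderate": 0.0, "heavy": 0.0},
        "male_adult": {"light": 0.20, "moderate": 0.35, "heavy": 0.45},
        "female_adult": {"light": 0.60, "moderate": 0.30, "heavy": 0.10},
        "elderly": {"light": 0.80, "moderate": 0.15, "heavy": 0.05},
    }


def _default_adoption() -> dict:
    # (base adoption probability, gradient on the logit per SD of log
    # expenditure) per base food group.
    return {
        "pulses": (0.22, 0.30),
        "nuts_seeds": (0.015, 0.40),
        "dairy": (0.19, 0.50),
        "meat_poultry_fish": (0.55, 0.40),
        "eggs": (0.12, 0.50),
        "dark_green_leafy_vegetables": (0.40, 0.10),
        "other_vitamin_a_fruits_vegetables": (0.02, 0.40),
        "other_vegetables": (0.99, 0.10),
        "other_fruits": (0.09, 0.50),
        "extra_grain": (0.55, 0.0),
        "sugar": (0.50, 0.10),
    }


@dataclass
class GeneratorConfig:
    """All generating parameters; defaults are the study conditions.

    ``expenditure_lognormal`` maps round label to (mu, sigma) of log
    per-capita monthly expenditure; ``round_effects`` holds the round-2
    multiplier on energy and on the fat energy share plus an additive round-2
    shift on every adoption logit; ``gradient_beta`` holds the effect of
    standardised log expenditure on log energy and on the fat share
    (proportion per SD). Probability tables must sum to 1 row-wise.
    """

    n_psu: int = 275
    households_per_psu: int = 20
    seed: int = 2011
    round_labels: tuple[str, str] = ("2011", "2018")
    n_strata: int = 7
    expenditure_lognormal: dict = field(default_factory=lambda: {
        "2011": (7.2237, 0.50), "2018": (7.3724, 0.50)})
    mean_household_size: float = 3.8  # members aged >= 2 y
    age_sex_structure: dict = field(default_factory=_default_age_sex_structure)
    occupation_pal_probs: dict = field(default_factory=_default_occupation_pal_probs)
    baseline_intake: dict = field(default_factory=_default_baseline_intake)
    round_effects: dict = field(default_factory=lambda: {
        "energy": 0.92, "fat_share": 1.30, "adoption_logit": 0.55})
    gradient_beta: dict = field(default_factory=lambda: {
        "energy_log": 0.06, "fat_share": 0.015})
    adoption: dict = field(default_factory=_default_adoption)
    intake_noise_cv: float = 0.25
    fat_share_noise_sd: float = 0.065  # person-day spread of the fat share
    protein_share_noise_sd: float = 0.008
    weight_sigma: float = 0.25

    def validate(self) -> None:
        if self.n_psu < 1 or self.households_per_psu < 1:
            raise ConfigError("n_psu and households_per_psu must be >= 1")
        if len(set(self.round_labels)) != 2:
            raise ConfigError("exactly two distinct round labels required")
        total = sum(self.age_sex_structure.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigError(f"age_sex_structure sums to {total}, expected 1")
        for key, probs in self.occupation_pal_probs.items():
            s = sum(probs.values())
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ConfigError(f"occupation_pal_probs[{key!r}] sums to {s}")
        for band_sex, (e, p, f) in self.baseline_intake.items():
            if e <= 0 or not (0 < p < 1) or not (0 < f < 1):
                raise ConfigError(f"bad baseline_intake for {band_sex}")
        if self.intake_noise_cv < 0:
            raise ConfigError("intake_noise_cv must be >= 0")


# occupation names per PAL level (the codebook the default pal_map covers)
_OCC_BY_LEVEL = {
    "light": ("student", "homemaker", "none", "retired"),
    "moderate": ("trader", "service"),
    "heavy": ("farmer", "laborer"),
}

# body weight (kg) by age knots, interpolated linearly, lognormal spread
_WEIGHT_KNOTS_AGE = np.array([2.0, 5.0, 10.0, 15.0, 19.0, 30.0, 60.0, 90.0])
_WEIGHT_KNOTS = {
    "male": np.array([12.0, 18.0, 30.0, 48.0, 55.0, 58.0, 55.0, 50.0]),
    "female": np.array([11.5, 17.0, 30.0, 45.0, 48.0, 50.0, 48.0, 44.0]),
}


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: GeneratorConfig) -> dict:
    """Generate the four survey tables plus a ground-truth record.

    Returns ``{"households", "persons", "food_records", "fct", "truth"}``;
    deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fct = make_fixture_fct()

    # effective per-gram (as purchased) nutrient content
    eff = fct.set_index("item_name")
    per_g = {
        n: (
            float(eff.loc[n, "protein_g_100g"]) * float(eff.loc[n, "edible_coeff"]) / 100.0,
            float(eff.loc[n, "fat_g_100g"]) * float(eff.loc[n, "edible_coeff"]) / 100.0,
            float(eff.loc[n, "carb_g_100g"]) * float(eff.loc[n, "edible_coeff"]) / 100.0,
        )
        for n in eff.index
    }
    A = np.array([per_g[a] for a in ADJUSTERS]).T  # rows P,F,C x cols adjusters
    A_inv = np.linalg.inv(A)

    base_items = {}  # group -> list of item names (adjusters excluded)
    for row in _FCT_ITEMS:
        name, mddw = row[0], row[5]
        if name in ADJUSTERS:
            continue
        base_items.setdefault(mddw, []).append(name)
    base_items["extra_grain"] = ["wheat flour", "potato"]
    base_items["sugar"] = ["sugar"]
    base_items.pop("grains_roots_tubers", None)
    base_items.pop("other", None)

    base_grams = {
        "pulses": 25.0, "nuts_seeds": 10.0, "dairy": 80.0,
        "meat_poultry_fish": 55.0, "eggs": 40.0,
        "dark_green_leafy_vegetables": 50.0,
        "other_vitamin_a_fruits_vegetables": 45.0, "other_vegetables": 120.0,
        "other_fruits": 60.0, "extra_grain": 70.0, "sugar": 15.0,
    }

    bands = list(_BANDS)
    cells = list(config.age_sex_structure.keys())
    cell_probs = np.array([config.age_sex_structure[c] for c in cells])
    sigma_noise = math.sqrt(math.log(1.0 + config.intake_noise_cv ** 2))

    households_out, persons_out, record_parts = [], [], []
    shrink_count = 0
    total_persons = 0

    for r_idx, r_label in enumerate(config.round_labels):
        n_hh = config.n_psu * config.households_per_psu
        psu_idx = np.repeat(np.arange(config.n_psu), config.households_per_psu)
        psu_id = np.array([f"P{i:04d}" for i in psu_idx])
        stratum_id = np.array([f"S{i % config.n_strata}" for i in psu_idx])
        hh_id = np.array([f"{r_label}-H{j:05d}" for j in range(n_hh)])
        weight = rng.lognormal(0.0, config.weight_sigma, n_hh)
        size = 1 + rng.poisson(config.mean_household_size - 1.0, n_hh)
        size = np.clip(size, 1, 9)
        mu, sigma = config.expenditure_lognormal[r_label]
        pc_exp = rng.lognormal(mu, sigma, n_hh)
        z_hh = (np.log(pc_exp) - mu) / sigma

        households_out.append(pd.DataFrame({
            "household_id": hh_id, "psu_id": psu_id, "stratum_id": stratum_id,
            "round": r_label, "sampling_weight": weight,
            "monthly_expenditure": pc_exp * size, "n_members": size,
        }))

        # ---- persons -----------------------------------------------------
        n_p = int(size.sum())
        total_persons += n_p
        hh_of = np.repeat(np.arange(n_hh), size)
        member_no = np.concatenate([np.arange(s) for s in size])
        person_id = np.array(
            [f"{h}-M{m}" for h, m in zip(hh_id[hh_of], member_no)]
        )
        cell_draw = rng.choice(len(cells), size=n_p, p=cell_probs)
        band = np.array([cells[i][0] for i in cell_draw])
        sex = np.array([cells[i][1] for i in cell_draw])
        lo = np.array([_BAND_EDGES[b][0] for b in band])
        hi = np.array([_BAND_EDGES[b][1] for b in band])
        age = lo + (hi - lo) * rng.random(n_p)

        wt = np.empty(n_p)
        for s in ("male", "female"):
            m = sex == s
            wt[m] = np.interp(age[m], _WEIGHT_KNOTS_AGE, _WEIGHT_KNOTS[s])
        wt *= rng.lognormal(0.0, 0.12, n_p)

        occ_group = np.where(
            age < 19, "child",
            np.where(age >= 61, "elderly",
                     np.where(sex == "male", "male_adult", "female_adult")),
        )
        level = np.empty(n_p, dtype=object)
        for g, probs in config.occupation_pal_probs.items():
            m = occ_group == g
            if not m.any():
                continue
            names = list(probs.keys())
            level[m] = rng.choice(names, size=int(m.sum()),
                                  p=[probs[k] for k in names])
        occ = np.empty(n_p, dtype=object)
        for lvl, choices in _OCC_BY_LEVEL.items():
            m = level == lvl
            if not m.any():
                continue
            if lvl == "light":
                # children are students; adults homemakers/none
                is_child = m & (age < 19)
                occ[is_child] = "student"
                rest = m & ~is_child
                occ[rest] = rng.choice(["homemaker", "none"], size=int(rest.sum()))
            else:
                occ[m] = rng.choice(choices, size=int(m.sum()))

        persons_out.append(pd.DataFrame({
            "person_id": person_id, "household_id": hh_id[hh_of],
            "round": r_label, "age_years": age, "sex": sex,
            "body_weight_kg": wt, "occupation_class": occ.astype(str),
        }))

        # ---- person-day macro targets ------------------------------------
        z = z_hh[hh_of]
        e_base = np.array([config.baseline_intake[(b, s)][0]
                           for b, s in zip(band, sex)])
        p_base = np.array([config.baseline_intake[(b, s)][1]
                           for b, s in zip(band, sex)])
        f_base = np.array([config.baseline_intake[(b, s)][2]
                           for b, s in zip(band, sex)])
        e_mult = config.round_effects["energy"] if r_idx == 1 else 1.0
        f_mult = config.round_effects["fat_share"] if r_idx == 1 else 1.0
        energy = (e_base * e_mult
                  * np.exp(config.gradient_beta["energy_log"] * z)
                  * rng.lognormal(0.0, sigma_noise, n_p))
        f_share = np.clip(
            f_base * f_mult + config.gradient_beta["fat_share"] * z
            + rng.normal(0.0, config.fat_share_noise_sd, n_p),
            0.06, 0.40,
        )
        p_share = np.clip(
            p_base + rng.normal(0.0, config.protein_share_noise_sd, n_p),
            0.085, 0.16,
        )
        c_share = 1.0 - p_share - f_share
        targets = np.vstack([
            p_share * energy / 4.0, f_share * energy / 9.0,
            c_share * energy / 4.0,
        ])  # (3, n_p) grams of P, F, C

        # ---- base diet ----------------------------------------------------
        scale = e_base / 2780.0  # children eat child-sized base portions
        base_nutr = np.zeros((3, n_p))
        adopt_shift = (config.round_effects.get("adoption_logit", 0.0)
                       if r_idx == 1 else 0.0)
        part_idx, part_item, part_qty = [], [], []
        for group in sorted(base_items):
            p0, beta = config.adoption.get(group, (0.0, 0.0))
            if p0 <= 0:
                continue
            logit_p = _logit(np.clip(p0, 1e-6, 1 - 1e-6)) + beta * z + adopt_shift
            adopted = rng.random(n_p) < _expit(logit_p)
            idx = np.flatnonzero(adopted)
            if idx.size == 0:
                continue
            items = base_items[group]
            pick = rng.integers(0, len(items), size=idx.size)
            grams = (base_grams[group] * scale[idx]
                     * rng.lognormal(0.0, 0.4, idx.size))
            for k, item in enumerate(items):
                m = pick == k
                if not m.any():
                    continue
                gpp = per_g[item]
                for nut in range(3):
                    base_nutr[nut, idx[m]] += gpp[nut] * grams[m]
                part_idx.append(idx[m])
                part_item.append(np.full(int(m.sum()), item))
                part_qty.append(grams[m])

        # ---- solve adjuster grams, shrinking the base diet if needed -----
        amt_t = A_inv @ targets
        amt_b = A_inv @ base_nutr
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(amt_b > 1e-12, amt_t / amt_b, np.inf)
        s = np.minimum(1.0, 0.999 * ratios.min(axis=0))
        s = np.clip(s, 0.0, 1.0)
        shrink_count += int((s < 1.0).sum())
        adj = amt_t - s * amt_b  # (3, n_p) grams of each adjuster
        adj = np.maximum(adj, 0.0)  # numerical guard; exact solve is >= 0

        # apply the shrink factor to the already-emitted base records
        part_qty = [q * s[i] for q, i in zip(part_qty, part_idx)]
        for k, name in enumerate(ADJUSTERS):
            part_idx.append(np.arange(n_p))
            part_item.append(np.full(n_p, name))
            part_qty.append(adj[k])

        record_parts.append(pd.DataFrame({
            "person_id": person_id[np.concatenate(part_idx)],
            "round": r_label,
            "item_name": np.concatenate(part_item),
            "quantity_g": np.concatenate(part_qty),
        }))

    households = pd.concat(households_out, ignore_index=True)
    persons = pd.concat(persons_out, ignore_index=True)
    food_records = (
        pd.concat(record_parts, ignore_index=True)
        .sort_values(["round", "person_id", "item_name"], kind="stable")
        .reset_index(drop=True)
    )
    food_records = food_records[food_records["quantity_g"] > 0].reset_index(drop=True)

    truth = {
        "seed": config.seed,
        "round_labels": list(config.round_labels),
        "round_effect_energy": config.round_effects["energy"],
        "round_effect_fat_share": config.round_effects["fat_share"],
        "adoption_logit_round_shift": config.round_effects.get("adoption_logit", 0.0),
        "energy_gradient_log_per_sd": config.gradient_beta["energy_log"],
        "fat_share_gradient_per_sd": config.gradient_beta["fat_share"],
        "intake_noise_cv": config.intake_noise_cv,
        "n_psu": config.n_psu,
        "households_per_psu": config.households_per_psu,
        "n_persons": total_persons,
        "base_shrink_rate": shrink_count / max(total_persons, 1),
        "adoption": {g: list(v) for g, v in config.adoption.items()},
        "baseline_intake": {f"{b}|{s}": list(v)
                            for (b, s), v in config.baseline_intake.items()},
    }
    return {"households": households, "persons": persons,
            "food_records": food_records, "fct": fct, "truth": truth}


# ---------------------------------------------------------------------------
# reduced generators for statistical calibration studies


def simulate_null_prevalence(
    n_psu: int,
    persons_per_psu_round: int,
    p: float,
    rng: np.random.Generator,
    *,
    sd_psu: float = 0.3,
    sd_round: float = 0.15,
    weight_sigma: float = 0.25,
    round_labels: tuple[str, str] = ("2011", "2018"),
) -> pd.DataFrame:
    """Null two-round clustered binary survey at the outcome level.

    Both rounds share the same prevalence process: PSU effects (shared across
    rounds) and round-specific PSU effects perturb the logit of *p*; persons
    are Bernoulli within PSU. Used to calibrate the adjusted Wald test's
    type-I error without the food-record machinery.
    """
    u = rng.normal(0.0, sd_psu, n_psu)
    frames = []
    for r_label in round_labels:
        v = rng.normal(0.0, sd_round, n_psu)
        p_psu = _expit(_logit(np.clip(p, 1e-9, 1 - 1e-9)) + u + v)
        psu = np.repeat(np.arange(n_psu), persons_per_psu_round)
        y = rng.random(n_psu * persons_per_psu_round) < p_psu[psu]
        frames.append(pd.DataFrame({
            "round": r_label,
            "psu_id": np.array([f"P{i:04d}" for i in psu]),
            "stratum_id": "S0",
            "sampling_weight": rng.lognormal(0.0, weight_sigma, len(psu)),
            "y": y.astype(float),
        }))
    return pd.concat(frames, ignore_index=True)


def rank_linear_outcome(
    ranks: np.ndarray,
    intercept_pct: float,
    slope_pp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary outcome with prevalence linear in fractional rank.

    ``P(y=1 | r) = (intercept_pct + slope_pp * r) / 100`` (clipped to [0,1]);
    the population SII of the generated outcome is *slope_pp* by
    construction.
    """
    prob = np.clip((intercept_pct + slope_pp * np.asarray(ranks)) / 100.0, 0, 1)
    return (rng.random(len(prob)) < prob).astype(float)
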