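"""End-to-end orchestration: simulate or ingest, then every analysis stage.

The pipeline is deterministic given inputs and seed. Each output CSV gets a
JSON metadata sidecar carrying the seed and a hash of the run configuration,
and the run log tallies record conservation at every stage (rows in = rows
out + rows excluded, with reasons), so the analysis denominators are
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import adequacy, diversity, equity, nutrients, synthetic, trends
from .config import AnalysisConfig, load_config
from .core import SurveyDesign
from .errors import DietIQError
from .io import read_tables, write_tables


@dataclass
class RunConfig:
    """Pipeline run parameters: either an input directory or a generator."""

    out_dir: str
    seed: int = 0
    input_dir: str | None = None  # read households/persons/food_records/fct
    generator: synthetic.GeneratorConfig | None = None
    analysis: AnalysisConfig | None = None
    strict_matching: bool = True
    design: SurveyDesign = field(default_factory=SurveyDesign)


def _config_hash(cfg: RunConfig) -> str:
    # dataclass repr is deterministic for identical construction
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]


def _sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the output tables plus the run log.

    Stages: (simulate | read) -> nutrient totals -> diversity -> adequacy ->
    expenditure ranks -> equity indices -> round trends. Any stage error is
    re-raised with the stage name attached.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = cfg.analysis or load_config()
    design = cfg.design
    meta = {"seed": cfg.seed, "config_hash": _config_hash(cfg)}
    log: dict = {"stages": [], "meta": meta}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except DietIQError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    truth = None
    if cfg.generator is not None:
        gen_cfg = dataclasses.replace(cfg.generator, seed=cfg.seed)
        bundle = stage("simulate", synthetic.generate, gen_cfg)
        truth = bundle.pop("truth")
        tables = bundle
    elif cfg.input_dir is not None:
        paths = {k: Path(cfg.input_dir) / f"{k}.csv"
                 for k in ("households", "persons", "food_records", "fct")}
        tables, diags = stage("read", read_tables, paths,
                              atwater=analysis.atwater,
                              fct_consistency_band=analysis.fct_consistency_band)
        log["read_diagnostics"] = [dataclasses.asdict(d) for d in diags]
    else:
        raise DietIQError("RunConfig needs input_dir or generator")

    households, persons = tables["households"], tables["persons"]
    records, fct = tables["food_records"], tables["fct"]
    n_persons = len(persons)

    # --- nutrients --------------------------------------------------------
    matched, match_report = stage(
        "match_items", nutrients.match_items, records, fct,
        strict=cfg.strict_matching,
    )
    resolvable = matched[matched["item_key"].notna()]
    intakes = stage(
        "nutrients", nutrients.compute_intakes, resolvable, fct,
        atwater=analysis.atwater,
        intake_consistency_band=analysis.intake_consistency_band,
    )
    n_zero = int(intakes["zero_energy"].sum())
    log["stages"].append({
        "stage": "nutrients", "rows_in": len(records),
        "rows_matched": len(resolvable),
        "excluded": {"unmatched_records": len(records) - len(resolvable)},
        "person_days": len(intakes), "zero_energy_days": n_zero,
        "match_report": dataclasses.asdict(match_report),
    })

    # persons without any food record never enter the intake table
    recorded = set(zip(intakes["person_id"], intakes["round"]))
    covered = [
        (p, r) in recorded for p, r in zip(persons["person_id"], persons["round"])
    ]
    persons_covered = persons[pd.Series(covered, index=persons.index)]
    log["stages"].append({
        "stage": "coverage", "rows_in": n_persons,
        "rows_out": len(persons_covered),
        "excluded": {"no_food_records": n_persons - len(persons_covered)},
    })

    # --- diversity --------------------------------------------------------
    div = stage(
        "diversity", diversity.score_diversity_table, intakes, fct,
        persons_covered,
        scheme_switch_age=analysis.scheme_switch_age,
        who7_threshold=analysis.who7_threshold,
        mddw_threshold=analysis.mddw_threshold,
    )

    # --- adequacy (positive-energy person-days only) ----------------------
    intakes_pos = intakes[~intakes["zero_energy"]]
    adq = stage(
        "adequacy", adequacy.classify_adequacy, intakes_pos, persons_covered,
        bmr_coeffs=analysis.bmr_coefficients, amdr=analysis.amdr,
        pal_map=analysis.pal_map, pal_levels=analysis.pal_levels,
        energy_threshold=analysis.energy_threshold,
    )
    log["stages"].append({
        "stage": "adequacy", "rows_in": len(intakes),
        "rows_out": len(adq), "excluded": {"zero_energy_days": n_zero},
    })

    # --- equity -----------------------------------------------------------
    ranked = stage("ranks", equity.attach_expenditure_ranks,
                   persons_covered, households, design)
    flags = adq.copy()
    flags["protein_insufficient"] = flags["protein_status"] == adequacy.INSUFFICIENT
    flags["fat_insufficient"] = flags["fat_status"] == adequacy.INSUFFICIENT
    flags["carb_excessive"] = flags["carb_status"] == adequacy.EXCESSIVE
    outcome_cols = ["energy_insufficient", "protein_insufficient",
                    "fat_insufficient", "carb_excessive"]
    eq = stage("equity", equity.equity_results, flags, ranked, design,
               analysis.bands, outcome_cols)
    equiplot = eq[["outcome", "band", "sex", "round", "n"]
                  + [f"prev_{q}" for q in equity.QUINTILES]]

    # --- trends -----------------------------------------------------------
    enriched = intakes_pos.merge(
        ranked[["person_id", "round", "age_years", "sex",
                design.weight_col, design.psu_col, design.stratum_col]],
        on=["person_id", "round"], validate="one_to_one",
    )
    cells = stage(
        "cell_summaries", trends.summarize_cells, enriched, design,
        analysis.bands, ["energy_kcal", "protein_g", "fat_g", "carb_g"],
    )
    rounds = tuple(sorted(persons["round"].unique()))
    trend_rows = []
    for (band, sex), cell in enriched.assign(
        band=[c for c in map(lambda a: _band_label(a, analysis), enriched["age_years"])]
    ).groupby(["band", "sex"], sort=True):
        for measure in ("energy_kcal", "protein_g", "fat_g", "carb_g"):
            try:
                tr = trends.intake_ratio(
                    cell[measure].to_numpy(), cell["round"].to_numpy(),
                    cell[design.weight_col].to_numpy(),
                    cell[design.psu_col].to_numpy(), rounds, measure=measure,
                )
            except DietIQError:
                continue
            trend_rows.append({
                "band": band, "sex": sex, "measure": measure,
                "ratio": tr.ratio, "ci_low": tr.ci_low, "ci_high": tr.ci_high,
                "p_value": tr.p_value, "stars": trends.significance_stars(tr.p_value),
                "test": tr.test, "n_excluded_zero": tr.n_excluded_zero,
            })
    trend_results = pd.DataFrame(trend_rows)

    outputs = {
        "person_day_intakes": intakes,
        "diversity": div,
        "adequacy": adq,
        "equity_results": eq,
        "equiplot_data": equiplot,
        "trend_results": trend_results,
        "cell_summaries": cells,
    }
    written = write_tables(outputs, out_dir)
    for path in written.values():
        _sidecar(path, meta)
    if truth is not None:
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str))
    outputs["run_log"] = log
    outputs["truth"] = truth
    return outputs


def _band_label(age: float, analysis: AnalysisConfig) -> str:
    from .core import assign_age_band

    return assign_age_band(float(age), analysis.bands).label
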