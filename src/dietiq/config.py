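"""Analysis configuration: bundled defaults plus YAML overrides."""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .adequacy import AMDRTable, BMRCoefficientTable
from .core import AgeBand, validate_bands
from .errors import ConfigError


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, resolved into typed objects."""

    bands: list[AgeBand]
    amdr: AMDRTable
    bmr_coefficients: BMRCoefficientTable
    pal_levels: dict[str, float]
    pal_map: dict[str, str]
    atwater: dict[str, float] = field(
        default_factory=lambda: {"protein": 4.0, "fat": 9.0, "carb": 4.0}
    )
    energy_threshold: float = 0.85
    fct_consistency_band: tuple[float, float] = (0.70, 1.30)
    intake_consistency_band: tuple[float, float] = (0.90, 1.10)
    scheme_switch_age: float = 10.0
    who7_threshold: int = 4
    mddw_threshold: int = 5


def _band(rec: Mapping) -> AgeBand:
    upper = rec["upper"]
    upper = math.inf if upper in (".inf", "inf", None) else float(upper)
    return AgeBand(str(rec["label"]), float(rec["lower"]), upper)


def load_config(path: str | None = None) -> AnalysisConfig:
    """Load the bundled defaults, optionally overridden by a YAML file.

    Overrides replace whole top-level keys (a partial ``amdr`` list is not
    merged row-wise).
    """
    raw = yaml.safe_load(
        importlib.resources.files("dietiq.data").joinpath("defaults.yaml").read_text()
    )
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        raw.update(override)
    return from_dict(raw)


def from_dict(raw: Mapping) -> AnalysisConfig:
    bands = [_band(rec) for rec in raw["age_bands"]]
    validate_bands(bands)
    levels = {str(k): float(v) for k, v in raw["pal_levels"].items()}
    pal_map = {str(k): str(v) for k, v in raw["pal_map"].items()}
    bad = set(pal_map.values()) - set(levels)
    if bad:
        raise ConfigError(f"PAL map references unknown levels: {sorted(bad)}")
    div = raw.get("diversity", {})
    return AnalysisConfig(
        bands=bands,
        amdr=AMDRTable.from_records(raw["amdr"]),
        bmr_coefficients=BMRCoefficientTable.from_records(raw["bmr_coefficients"]),
        pal_levels=levels,
        pal_map=pal_map,
        atwater={str(k): float(v) for k, v in raw["atwater"].items()},
        energy_threshold=float(raw.get("energy_threshold", 0.85)),
        fct_consistency_band=tuple(raw.get("fct_consistency_band", (0.70, 1.30))),
        intake_consistency_band=tuple(raw.get("intake_consistency_band", (0.90, 1.10))),
        scheme_switch_age=float(div.get("scheme_switch_age", 10.0)),
        who7_threshold=int(div.get("who7_threshold", 4)),
        mddw_threshold=int(div.get("mddw_threshold", 5)),
    )
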