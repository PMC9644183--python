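"""Shared domain types: age bands, survey design, food-group schemes.

The pipeline's working containers are pandas DataFrames (see :mod:`dietiq.io`
for the column schemas); the dataclasses here carry the configuration-like
objects that every stage shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError, OutOfScopeError

SEXES = ("male", "female")

#: Minimum age (years) of the analysis population. Younger household members
#: are out of scope for the dietary analysis.
MIN_ANALYSIS_AGE = 2.0

#: The ten MDD-W food groups (women/adolescent scheme). Items that belong to
#: no counted group (oils, sugar, condiments) carry ``NOT_COUNTED`` and never
#: contribute to a diversity score.
MDDW_GROUPS = (
    "grains_roots_tubers",
    "pulses",
    "nuts_seeds",
    "dairy",
    "meat_poultry_fish",
    "eggs",
    "dark_green_leafy_vegetables",
    "other_vitamin_a_fruits_vegetables",
    "other_vegetables",
    "other_fruits",
)

#: The seven WHO child food groups (ages below the scheme switch).
WHO7_GROUPS = (
    "grains_roots_tubers",
    "legumes_nuts",
    "dairy",
    "flesh_foods",
    "eggs",
    "vitamin_a_fruits_vegetables",
    "other_fruits_vegetables",
)

NOT_COUNTED = "other"


@dataclass(frozen=True)
class AgeBand:
    """Reporting age band ``[lower_incl, upper_excl)`` in years."""

    label: str
    lower_incl: float
    upper_excl: float  # math.inf for the open-ended last band

    def contains(self, age_years: float) -> bool:
        return self.lower_incl <= age_years < self.upper_excl


@dataclass(frozen=True)
class SurveyDesign:
    """Column designators for design-based estimation.

    Every record entering a weighted estimator must carry a positive weight
    and a PSU (cluster) id under these column names.
    """

    weight_col: str = "sampling_weight"
    psu_col: str = "psu_id"
    stratum_col: str = "stratum_id"


def validate_bands(bands: Sequence[AgeBand], lower: float = MIN_ANALYSIS_AGE) -> None:
    """Check that *bands* partition ``[lower, inf)`` without gaps or overlaps.

    Raises :class:`ConfigError` otherwise.
    """
    if not bands:
        raise ConfigError("empty age-band list")
    ordered = sorted(bands, key=lambda b: b.lower_incl)
    if not math.isclose(ordered[0].lower_incl, lower):
        raise ConfigError(
            f"bands must start at {lower}, got {ordered[0].lower_incl}"
        )
    for a, b in zip(ordered, ordered[1:]):
        if not math.isclose(a.upper_excl, b.lower_incl):
            raise ConfigError(
                f"bands {a.label!r} and {b.label!r} do not tile: "
                f"{a.upper_excl} != {b.lower_incl}"
            )
    if not math.isinf(ordered[-1].upper_excl):
        raise ConfigError("last band must be open-ended (upper_excl = inf)")
    labels = [b.label for b in bands]
    if len(set(labels)) != len(labels):
        raise ConfigError("band labels must be distinct")


def assign_age_band(age_years: float, bands: Sequence[AgeBand]) -> AgeBand:
    """Return the unique band containing *age_years* (lower-in, upper-out).

    Ages below the analysis minimum raise :class:`OutOfScopeError`.
    """
    if age_years < MIN_ANALYSIS_AGE:
        raise OutOfScopeError(
            f"age {age_years} y is below the analysis minimum "
            f"({MIN_ANALYSIS_AGE} y)"
        )
    for band in bands:
        if band.contains(age_years):
            return band
    raise ConfigError(f"no band covers age {age_years} y")
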