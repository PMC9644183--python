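"""Exception hierarchy.

Every stage raises a subclass of :class:`DietIQError` so pipeline callers can
attach stage context without string-matching messages.
"""


class DietIQError(Exception):
    """Base class for all package errors."""


class SchemaError(DietIQError):
    """A required column is missing or has an unusable dtype."""


class ValidationError(DietIQError):
    """A row violates a type invariant (e.g. non-positive sampling weight)."""


class ReferentialError(DietIQError):
    """A join key points at a record that does not exist.

    Carries the offending keys in :attr:`orphans`.
    """

    def __init__(self, message: str, orphans=()):
        super().__init__(message)
        self.orphans = list(orphans)


class ConfigError(DietIQError):
    """A configuration value is inconsistent (probabilities, band overlaps...)."""


class OutOfScopeError(DietIQError):
    """The record falls outside the analysis population (e.g. age < 2 y)."""


class UnresolvedItemError(DietIQError):
    """A food item could not be matched against any composition table."""

    def __init__(self, message: str, items=()):
        super().__init__(message)
        self.items = list(items)


class UndefinedSharesError(DietIQError):
    """Energy shares requested for a zero-energy person-day."""


class CoefficientGapError(DietIQError):
    """No BMR coefficient row covers the requested sex/age."""


class DegenerateDistributionError(DietIQError):
    """Quantile cutpoints undefined (all values identical)."""


class UndefinedIndexError(DietIQError):
    """Concentration index undefined (weighted outcome mean is zero)."""


class EstimationError(DietIQError):
    """A model could not be estimated (empty round, singular design, <2 PSUs)."""


class UndefinedChangeError(DietIQError):
    """Percent change from a zero baseline."""
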