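"""Exception hierarchy for gutharvest.

All package-specific failures derive from :class:`GutHarvestError` so callers
can catch one base class; subclasses mirror the distinct failure modes of the
pipeline (insufficient data for a regression, unphysical parameter values,
degenerate designs, taxonomy-rank misuse, configuration problems).
"""


class GutHarvestError(Exception):
    """Base class for all gutharvest errors."""


class InsufficientDataError(GutHarvestError):
    """Too few observations for the requested fit (e.g. < 3 OD points)."""


class DomainError(GutHarvestError, ValueError):
    """A value lies outside its physically meaningful domain."""


class DegenerateDesignError(GutHarvestError):
    """The regression design matrix is singular (e.g. all OD values equal)."""


class RankError(GutHarvestError):
    """Requested taxonomic rank is finer than the table provides."""


class NoRepresentationError(GutHarvestError):
    """No characterized strain matches any taxon with non-zero abundance."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "no characterized strain represents any abundant taxon; "
            f"unmatched taxa: {', '.join(self.missing[:10])}"
        )


class ConfigError(GutHarvestError):
    """Unknown scenario/config key or invalid configuration value."""


class UnitsError(GutHarvestError):
    """Inconsistent units between combined quantities."""
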