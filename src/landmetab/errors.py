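"""Exception hierarchy for the landmetab pipeline.

All package errors derive from :class:`LandmetabError` so callers can catch
one base class; the subclasses distinguish bad arguments, bad configuration,
bad input data and empty results, which the CLI maps onto exit codes.
"""


class LandmetabError(Exception):
    """Base class for all landmetab errors."""


class InvalidArgumentError(LandmetabError, ValueError):
    """A function argument is outside its documented domain."""


class InvalidConfigurationError(LandmetabError, ValueError):
    """A configuration value (thresholds, category counts, bands) is inconsistent."""


class ValidationError(LandmetabError, ValueError):
    """Input data violates a structural contract (codes, ranges, cross-references).

    ``details`` carries the individual failures so they can be reported together.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        super().__init__(message)
        self.details = list(details or [])

    def __str__(self) -> str:  # aggregate report, not first-failure-only
        base = super().__str__()
        if self.details:
            return base + "\n  - " + "\n  - ".join(self.details)
        return base


class EmptyResultError(LandmetabError):
    """An operation produced no usable result (e.g. all-nodata raster)."""


class DegenerateInputError(LandmetabError, ValueError):
    """Numerically degenerate input (e.g. zero-variance regressor)."""
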