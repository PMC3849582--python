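"""Exception hierarchy shared across the package."""


class PhenosetsError(Exception):
    """Base class for all package errors."""


class InvalidLabelError(PhenosetsError):
    """A gene label is empty or otherwise unparseable."""


class DialectError(PhenosetsError):
    """Unknown association-table dialect."""


class EmptyCollectionError(PhenosetsError):
    """An operation that requires at least one gene set received none."""


class NonRedundancyError(PhenosetsError):
    """Duplicate phenotype terms where a collection must be non-redundant."""


class UndefinedDistanceError(PhenosetsError):
    """Overlap distance is undefined (an empty gene set was supplied)."""


class ConfigurationError(PhenosetsError):
    """Invalid configuration (bad filter bounds, label mismatch, ...)."""


class FitError(PhenosetsError):
    """Least-squares tree fitting failed (singular design, duplicate leaves)."""


class NormalizationError(PhenosetsError):
    """Expression normalization failed (e.g. a zero-variance sample)."""


class DegenerateContrastError(PhenosetsError):
    """A contrast has zero spread, so scores are undefined."""


class EmptyResultError(PhenosetsError):
    """No gene set survived filtering/matching for this analysis."""


class DegenerateProjectionError(PhenosetsError):
    """The centered matrix is identically zero; no principal axes exist."""


class SpecError(PhenosetsError):
    """A synthetic-data specification is infeasible or inconsistent."""
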