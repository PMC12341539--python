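"""Exception hierarchy for the prejump pipeline.

Every error raised by the library derives from :class:`PrejumpError`, so
callers (and the CLI) can catch one base class and report the failing stage.
"""


class PrejumpError(Exception):
    """Base class for all prejump errors."""


class InvalidSpecificationError(PrejumpError, ValueError):
    """A moment specification is internally inconsistent (e.g. |r| >= 1)."""


class InfeasibleExactMatchError(PrejumpError, ValueError):
    """Exact moment matching is rank-infeasible at the requested sample size."""


class SingularDataError(PrejumpError, RuntimeError):
    """Random draws repeatedly produced a singular empirical covariance."""


class InsufficientPanelError(PrejumpError, ValueError):
    """An expert panel has fewer than two raters."""


class DiagnosticsUnavailableError(PrejumpError, ValueError):
    """A correlation matrix is singular, so KMO diagnostics are undefined."""


class DegenerateKMOError(PrejumpError, ZeroDivisionError):
    """All off-diagonal correlations are zero; KMO is a 0/0 form."""


class InvalidMatrixError(PrejumpError, ValueError):
    """A matrix violates the preconditions of a diagnostic (e.g. det <= 0)."""


class NormalizationError(PrejumpError, ValueError):
    """Mean normalization is undefined because the sequence mean is <= 0."""


class UndefinedCorrelationError(PrejumpError, ValueError):
    """Pearson correlation is undefined (zero variance or too few points)."""


class CohortParseError(PrejumpError, ValueError):
    """A cohort CSV is malformed; the message names the offending row/column."""


class ConfigError(PrejumpError, ValueError):
    """A pipeline configuration is invalid (unknown column, bad threshold)."""
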