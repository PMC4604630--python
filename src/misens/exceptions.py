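"""Exception hierarchy.

All misens errors derive from :class:`MisensError` so callers can catch the
package's failures with a single except clause; each also derives from
``ValueError`` because every one of them signals an invalid input or a
degenerate data configuration.
"""


class MisensError(ValueError):
    """Base class for all misens errors."""


class ParameterError(MisensError):
    """Invalid population or mechanism parameters."""


class DegenerateDataError(MisensError):
    """Data configuration too degenerate for the requested operation
    (e.g. too few complete cases, single-class indicator)."""


class ImputationModelError(MisensError):
    """The imputation model could not be fitted (separation, non-convergence)."""


class AnalysisError(MisensError):
    """The target analysis cannot be computed on the given data."""


class PoolingError(MisensError):
    """Invalid inputs to Rubin or weighted pooling."""


class WeightError(PoolingError):
    """Non-finite or otherwise invalid importance weights."""


class DiagnosticError(MisensError):
    """Invalid inputs to a weight diagnostic."""


class StudyError(MisensError):
    """A simulation study failed (e.g. too many failed replicates)."""
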