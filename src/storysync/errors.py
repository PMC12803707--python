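"""Exception types shared across the pipeline."""


class StorysyncError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StorysyncError, ValueError):
    """A parameter value is outside its documented range or infeasible."""


class InvalidInputError(StorysyncError, ValueError):
    """Input data violate a precondition (lengths, ordering, coverage)."""


class DegenerateDesignError(InvalidInputError):
    """A design matrix is rank deficient; message names the collinear columns."""


class SubgroupMismatchError(InvalidInputError):
    """Subjects assigned to one randomization subgroup have differing schedules."""


class ParseError(StorysyncError, ValueError):
    """A delimited input file is malformed; message cites the offending line."""


class DependencyError(StorysyncError, RuntimeError):
    """A pipeline stage was requested before its upstream outputs exist."""
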