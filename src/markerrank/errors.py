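"""Exception hierarchy for the markerrank pipeline."""


class MarkerRankError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MarkerRankError):
    """A configuration value violates its documented range or invariant."""


class InvalidInputError(MarkerRankError):
    """An operation received input outside its contract (empty sequence, bad alphabet...)."""


class MissingGeneError(MarkerRankError):
    """A gene required for an operation is absent from a genome."""


class IncompletePairError(MarkerRankError):
    """A genome pair lacks one or more markers and cannot be ranked."""


class InsufficientDataError(MarkerRankError):
    """Too few observations to compute the requested statistic."""


class UndefinedCorrelationError(MarkerRankError):
    """Correlation requested on a constant vector."""


class InvalidMatrixError(MarkerRankError):
    """Distance matrix is not symmetric/nonnegative/zero-diagonal."""


class IncompatibleTreesError(MarkerRankError):
    """Trees do not share the same leaf label set."""


class ParseError(MarkerRankError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class LayoutError(MarkerRankError):
    """A cohort directory does not follow the expected layout."""


class MissingStageError(MarkerRankError):
    """A pipeline output required by a later stage is absent."""
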