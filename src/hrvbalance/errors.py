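"""Exception hierarchy for the hrvbalance pipeline."""


class HRVError(Exception):
    """Base class for all hrvbalance errors."""


class InvalidParameterError(HRVError, ValueError):
    """A configuration or function parameter violates its contract."""


class InvalidInputError(HRVError, ValueError):
    """Input data violate a structural invariant (e.g. non-positive interval)."""


class TooShortError(HRVError, ValueError):
    """A series/segment is too short for the requested operation."""


class SegmentUnavailableError(HRVError, ValueError):
    """A protocol phase is too short to yield even the fallback segment."""


class UndefinedIndexError(HRVError, ArithmeticError):
    """A derived index (e.g. LHFND with LF+HF = 0) is undefined for the input."""


class DegenerateClusterError(HRVError, ValueError):
    """Clustering input cannot be split (all values identical)."""


class ParseError(HRVError, ValueError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
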