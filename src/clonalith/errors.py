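"""Exception hierarchy for clonalith."""


class ClonalithError(Exception):
    """Base class for all package errors."""


class ConfigError(ClonalithError):
    """Invalid simulation or analysis configuration."""


class ParseError(ClonalithError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class BundleError(ClonalithError):
    """Cross-file inconsistency in a tumor data bundle (e.g. sample-ID mismatch)."""


class InvariantViolation(ClonalithError):
    """A data-structure invariant was broken (e.g. overlapping segments)."""


class SimulationError(ClonalithError):
    """Inconsistent ground truth encountered while simulating (e.g. expected VAF > 1)."""


class InsufficientDataError(ClonalithError):
    """Too few observations to run the requested estimator."""


class PipelineError(ClonalithError):
    """Degenerate intermediate state that prevents continuing the analysis."""


class TreeRootError(ClonalithError):
    """No truncal cluster exists to root the clone tree."""


class UndefinedMetricError(ClonalithError):
    """A metric is undefined for the given inputs (e.g. fewer than two samples)."""
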