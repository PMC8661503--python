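"""Exception hierarchy shared across the pipeline stages."""


class CycleKinError(Exception):
    """Base class for all package errors."""


class ParameterError(CycleKinError, ValueError):
    """A kinetic / simulation / gating parameter violates its contract."""


class InsufficientDataError(CycleKinError, ValueError):
    """Too few observations (times, replicates, events) for the requested fit."""


class NoEstimateError(CycleKinError, ValueError):
    """A fit exists but cannot be inverted into kinetic parameters (e.g. slope <= 0)."""


class UndefinedIndexError(CycleKinError, ZeroDivisionError):
    """The exit index denominator (total EdU+ cells) is zero."""


class MissingControlError(CycleKinError, KeyError):
    """No matched negative-control sample for a (day, batch) being gated."""


class ConfigError(CycleKinError, ValueError):
    """A run configuration fails validation."""


class StageError(CycleKinError, RuntimeError):
    """A pipeline stage failed; message carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
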