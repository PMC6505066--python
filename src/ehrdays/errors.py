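"""Exception types shared across the package."""


class EhrDaysError(Exception):
    """Base class for all package errors."""


class ConfigError(EhrDaysError):
    """Raised when a configuration value is invalid or missing."""


class UnsupportedOperationError(EhrDaysError):
    """Raised when a caller requests a computation the data cannot support
    reliably (e.g. day-level ventilation detection, composite severity
    scores)."""


class StageError(EhrDaysError):
    """Raised when a pipeline stage fails; carries the stage name and the
    offending record keys so runs abort with actionable context."""

    def __init__(self, stage: str, message: str, keys=None):
        self.stage = stage
        self.keys = list(keys) if keys is not None else []
        super().__init__(f"[{stage}] {message}" + (f" keys={self.keys[:20]}" if self.keys else ""))
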