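"""Exception hierarchy.

All hemoqc errors derive from :class:`HemoqcError` so callers can catch the
package's failures with a single except clause while still distinguishing
configuration mistakes from data inconsistencies.
"""


class HemoqcError(Exception):
    """Base class for all hemoqc errors."""


class ConfigurationError(HemoqcError, ValueError):
    """Invalid user-supplied configuration (factor counts, probabilities...)."""


class StructuralError(HemoqcError, ValueError):
    """Malformed data structure: wrong shape, missing or duplicate rows."""


class ConsistencyError(HemoqcError, ValueError):
    """Data internally inconsistent (e.g. run levels disagree with the design)."""


class DomainError(HemoqcError, ValueError):
    """Numeric argument outside the mathematical domain of an operation."""


class EncodingError(HemoqcError, ValueError):
    """A record references a factor level that cannot be encoded."""


class TrainingError(HemoqcError, RuntimeError):
    """Network training failed (divergence / non-finite loss)."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class PipelineStageError(HemoqcError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
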