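"""Exception hierarchy for the pipeline."""


class ExoPatternError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ExoPatternError):
    """A configuration value violates its invariants (names the field)."""


class DataError(ExoPatternError):
    """Input tables are malformed, misaligned, or referentially broken."""


class DomainError(ExoPatternError):
    """An operation received a value outside its mathematical domain."""


class UsageError(ExoPatternError):
    """An operation was called with the wrong shape/arity of arguments."""


class SimulationError(ExoPatternError):
    """Count simulation produced a non-finite or overflowing expectation."""


class ParseError(DataError):
    """A text input could not be parsed; message carries the line number."""


class PipelineError(ExoPatternError):
    """A pipeline stage failed; message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
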