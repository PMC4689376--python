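"""Exception hierarchy shared across the toolkit."""


class LeaSurveyError(Exception):
    """Base class for all errors raised by leasurvey."""


class ConfigurationError(LeaSurveyError):
    """An invalid or infeasible configuration (simulation or pipeline)."""


class ParseError(LeaSurveyError):
    """A malformed input file; carries the offending line number if known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SequenceError(LeaSurveyError):
    """An invalid biological sequence (unknown residue, empty input, ...)."""
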