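"""Exception hierarchy shared across the pipeline."""


class EocrcError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EocrcError):
    """Invalid or inconsistent configuration (unknown dialect, bad keys...)."""


class CallsetFormatError(EocrcError):
    """A malformed input row; carries file, line number and offending field."""

    def __init__(self, path, line, field, message):
        self.path = str(path)
        self.line = line
        self.field = field
        super().__init__(f"{self.path}:{line}: field '{field}': {message}")


class DataError(EocrcError):
    """Semantically invalid data (conflicting duplicates, unknown samples...)."""


class DegenerateInputError(EocrcError):
    """Input on which the requested statistic is undefined (zero variance...)."""
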