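"""Exception hierarchy shared across the package."""


class PhenolinkError(Exception):
    """Base class for all package errors."""


class TerminologyParseError(PhenolinkError):
    """A pipe-delimited terminology file contains a malformed row."""

    def __init__(self, path, line_number, message):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{self.path}:{line_number}: {message}")


class TerminologyLoadError(PhenolinkError):
    """Cross-file referential integrity failed during loading."""


class ObservationParseError(PhenolinkError):
    """An observation TSV is structurally invalid."""


class ConfigurationError(PhenolinkError):
    """An invalid runtime configuration value."""


class NotFoundError(PhenolinkError, KeyError):
    """A requested concept or code is absent from the graph or view."""

    def __str__(self):  # KeyError quotes its payload; keep the message readable
        return Exception.__str__(self)
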