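"""Exception hierarchy shared across the package."""


class AcmineError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AcmineError):
    """Invalid or incomplete configuration (missing columns, empty rule sets, ...)."""


class FormatError(AcmineError):
    """A file could not be parsed in the expected dialect."""


class DepositionFormatError(FormatError):
    """Malformed deposition file; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class StructureError(AcmineError):
    """A SMILES string could not be parsed or curated."""


class EmptyDistributionError(AcmineError):
    """A statistic was requested on an empty potency-difference distribution."""


class ConsistencyError(AcmineError):
    """Two artifacts that must agree (e.g. sd vs combined networks) do not."""
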