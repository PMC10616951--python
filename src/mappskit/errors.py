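"""Exception hierarchy shared across the pipeline."""


class MappsKitError(Exception):
    """Base class for all package-specific errors."""


class ReferenceMismatchError(MappsKitError):
    """A substitution's expected residue does not match the construct."""


class OutOfBoundsError(MappsKitError):
    """A position or interval falls outside the construct sequence."""


class AlleleLookupError(MappsKitError):
    """An allele is missing from a frequency table or rank matrix."""


class CoverageError(MappsKitError):
    """No usable allele/rank information for a donor or locus."""


class AlignmentError(MappsKitError):
    """Two rank matrices cannot be compared position-by-position."""


class PairingError(MappsKitError):
    """Records that must be paired (donor/day/stimulus) do not match."""


class ConsistencyError(MappsKitError):
    """Internally inconsistent counts or intervals."""


class ConfigError(MappsKitError):
    """Invalid or incomplete run configuration / input files."""


class ParseError(ConfigError):
    """A table could not be parsed; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
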