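"""Exception hierarchy shared across the package."""


class PeplibError(Exception):
    """Base class for all peplib errors."""


class InvalidSequenceError(PeplibError, ValueError):
    """A peptide sequence contains a letter outside the working alphabet."""

    def __init__(self, sequence: str, position: int, letter: str):
        self.sequence = sequence
        self.position = position  # 1-based
        self.letter = letter
        super().__init__(
            f"invalid residue {letter!r} at position {position} in sequence {sequence!r}"
        )


class ParseError(PeplibError, ValueError):
    """A structured file (SD block, prm, PDB) could not be parsed."""

    def __init__(self, message: str, record_index: int | None = None):
        self.record_index = record_index
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)


class ConfigurationError(PeplibError, ValueError):
    """A docking or pipeline configuration value is invalid."""


class EmbeddingError(PeplibError, RuntimeError):
    """3D conformer embedding failed after bounded retries."""
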