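"""Named exceptions raised across the toolkit."""


class CesaKitError(Exception):
    """Base class for all cesakit errors."""


class FastaFormatError(CesaKitError):
    """Raised for empty or malformed FASTA input."""


class SequenceAlphabetError(CesaKitError):
    """Raised when a sequence contains a non-canonical residue letter."""

    def __init__(self, record_id: str, position: int, letter: str):
        self.record_id = record_id
        self.position = position  # 1-based
        self.letter = letter
        super().__init__(
            f"illegal residue {letter!r} in record {record_id!r} at position {position}"
        )


class GeneModelError(CesaKitError):
    """Raised for inconsistent gene models (overlaps, mixed strands, bad spans)."""


class CountsFormatError(CesaKitError):
    """Raised for malformed count matrices (duplicates, negatives, empties)."""


class PatternSyntaxError(CesaKitError):
    """Raised when a degenerate motif pattern string cannot be compiled."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (offset {offset})"
        super().__init__(message)


class WindowError(CesaKitError):
    """Raised for invalid hydropathy window parameters."""


class MissingDomainError(CesaKitError):
    """Raised when a rule requires a domain the protein does not carry."""


class AlignmentError(CesaKitError):
    """Raised for unusable alignments (ragged rows, no retained columns, too few taxa)."""


class DistanceError(CesaKitError):
    """Raised when a distance is undefined (saturated pair) or a matrix is invalid."""


class BootstrapError(CesaKitError):
    """Raised when too many bootstrap replicates are unusable."""


class GeneratorError(CesaKitError):
    """Raised when a synthetic template cannot be realized."""
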