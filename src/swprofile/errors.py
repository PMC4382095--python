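"""Exception types shared across the package."""


class SwprofileError(Exception):
    """Base class for all package errors."""


class ParameterError(SwprofileError, ValueError):
    """A user-supplied parameter violates its contract."""


class MatrixFormatError(SwprofileError, ValueError):
    """A substitution-matrix file is malformed or asymmetric."""


class SequenceFormatError(SwprofileError, ValueError):
    """A FASTA/FASTQ file is malformed."""


class ResidueError(SwprofileError, KeyError):
    """A sequence contains a residue outside the scoring alphabet."""

    def __init__(self, symbol: str, position: int, seq_id: str = ""):
        self.symbol = symbol
        self.position = position
        self.seq_id = seq_id
        where = f" in sequence {seq_id!r}" if seq_id else ""
        super().__init__(
            f"residue {symbol!r} at position {position}{where} is not in the scoring alphabet"
        )
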