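"""Substitution scoring for DNA/RNA/protein alignment.

A :class:`ScoringScheme` bundles an ordered residue alphabet, a symmetric
substitution matrix and a linear (per-column) gap penalty.  Matrices may be
built directly (simple match/mismatch schemes for nucleotides) or loaded
from NCBI-format text files (BLOSUM/PAM style), in which case the gap
penalty is supplied separately because matrix files carry none.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import MatrixFormatError, ParameterError, ResidueError

DNA_ALPHABET = "ACGTUN"

#: Default nucleotide scores.  The match score of 5.0 makes a relative score
#: of 5.0 mean "perfect match over the entire alignment"; mismatch and gap
#: magnitudes follow common DNA scheme ratios scaled to that match score.
DEFAULT_MATCH = 5.0
DEFAULT_MISMATCH = -3.0
DEFAULT_GAP = -8.0


@dataclass(frozen=True, eq=False)
class ScoringScheme:
    """Residue alphabet + symmetric substitution scores + linear gap penalty.

    Parameters
    ----------
    alphabet : str
        Ordered residue symbols; row/column order of ``matrix``.
    matrix : numpy.ndarray
        Square, symmetric array of substitution scores.
    gap_penalty : float
        Score added per gapped alignment column; must be negative.
    """

    alphabet: str
    matrix: np.ndarray
    gap_penalty: float
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=np.float64)
        k = len(self.alphabet)
        if mat.shape != (k, k):
            raise MatrixFormatError(
                f"matrix shape {mat.shape} does not match alphabet size {k}"
            )
        if not np.array_equal(mat, mat.T):
            raise MatrixFormatError("substitution matrix is not symmetric")
        if not self.gap_penalty < 0:
            raise ParameterError("gap penalty must be negative")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.alphabet)}
        )
        lut = np.full(256, -1, dtype=np.int64)
        for i, c in enumerate(self.alphabet):
            lut[ord(c)] = i
        object.__setattr__(self, "_lut", lut)

    @property
    def match_score(self) -> float:
        """Maximum diagonal value; the relative score of a perfect match."""
        return float(np.max(np.diag(self.matrix)))

    def substitution(self, a: str, b: str) -> float:
        try:
            return float(self.matrix[self._index[a], self._index[b]])
        except KeyError as exc:
            sym = a if a not in self._index else b
            raise ResidueError(sym, -1) from exc

    def encode(self, residues: str, seq_id: str = "") -> np.ndarray:
        """Map a residue string to alphabet indices (int64 array).

        Raises :class:`ResidueError` naming the first offending symbol and
        its 1-based position.
        """
        try:
            raw = np.frombuffer(residues.encode("latin-1"), dtype=np.uint8)
        except UnicodeEncodeError as exc:
            raise ResidueError(residues[exc.start], exc.start + 1, seq_id) from exc
        out = self._lut[raw]
        if (out < 0).any():
            pos = int(np.argmax(out < 0))
            raise ResidueError(residues[pos], pos + 1, seq_id)
        return out

    def to_ncbi(self) -> str:
        """Render the substitution matrix in NCBI text format."""
        arr = substitution_matrices.Array(
            alphabet=self.alphabet, dims=2, data=self.matrix
        )
        return str(arr)


def default_dna_scheme(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> ScoringScheme:
    """Simple nucleotide scheme over ``{A,C,G,T,U,N}``.

    Every identical pair of ``{A,C,G,T,U}`` scores ``match``; every other
    pair, including any pair involving the ambiguity code ``N``, scores
    ``mismatch``.
    """
    if not match > 0:
        raise ParameterError("match score must be positive")
    if not mismatch < 0:
        raise ParameterError("mismatch score must be negative")
    if not gap < 0:
        raise ParameterError("gap penalty must be negative")
    k = len(DNA_ALPHABET)
    mat = np.full((k, k), mismatch, dtype=np.float64)
    for i, c in enumerate(DNA_ALPHABET):
        if c != "N":
            mat[i, i] = match
    return ScoringScheme(DNA_ALPHABET, mat, gap)


def load_substitution_matrix(path, gap_penalty: float = DEFAULT_GAP) -> ScoringScheme:
    """Load an NCBI-format substitution matrix file (BLOSUM/PAM style).

    The file supplies the alphabet and substitution scores; the linear gap
    penalty is given separately because matrix files carry none.
    """
    try:
        if hasattr(path, "read"):
            arr = substitution_matrices.read(path)
        else:
            with open(path) as handle:
                arr = substitution_matrices.read(handle)
    except Exception as exc:  # malformed/truncated file
        raise MatrixFormatError(f"cannot parse substitution matrix: {exc}") from exc
    alphabet = "".join(arr.alphabet)
    return ScoringScheme(alphabet, np.asarray(arr), gap_penalty)


def loads_substitution_matrix(text: str, gap_penalty: float = DEFAULT_GAP) -> ScoringScheme:
    """As :func:`load_substitution_matrix` but from a string."""
    return load_substitution_matrix(io.StringIO(text), gap_penalty)
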