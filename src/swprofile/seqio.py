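"""Sequence I/O, reverse complement and batch assembly.

A batch packs X query sequences padded to a common length N and Y targets
padded to length M into two flat strings ``x`` (length X*N) and ``y``
(length Y*M), the layout a data-parallel aligner consumes.  The pad symbol
is reserved (outside the scoring alphabet) and is never scored: each pair's
alignment runs over the true lengths only, so results are invariant to
batch composition and padding.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ParameterError, SequenceFormatError, SwprofileError

DEFAULT_PAD = "#"
_NUCLEOTIDES = set("ACGTUNacgtun")


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; ``source`` marks its batch role."""

    id: str
    residues: str
    source: str = "query"

    def __post_init__(self):
        if not self.id:
            raise ParameterError("sequence id must be non-empty")
        if not self.residues:
            raise ParameterError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class BatchLayout:
    """X queries padded to N and Y targets padded to M, flattened."""

    queries: tuple
    targets: tuple
    pad_symbol: str
    N: int
    M: int

    @property
    def X(self) -> int:
        return len(self.queries)

    @property
    def Y(self) -> int:
        return len(self.targets)

    @property
    def x(self) -> str:
        return "".join(q.residues.ljust(self.N, self.pad_symbol) for q in self.queries)

    @property
    def y(self) -> str:
        return "".join(t.residues.ljust(self.M, self.pad_symbol) for t in self.targets)

    @property
    def true_lengths(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return (
            tuple(len(q) for q in self.queries),
            tuple(len(t) for t in self.targets),
        )


def read_sequences(path, fmt: str = "fasta", source: str = "query") -> list[SequenceRecord]:
    """Parse a FASTA or FASTQ file into records, preserving file order.

    FASTQ qualities are read (and validated by the parser) but unused.
    Duplicate ids are rejected.
    """
    if fmt not in ("fasta", "fastq"):
        raise ParameterError(f"unsupported format {fmt!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(path, fmt):
            if rec.id in seen:
                raise SequenceFormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper(), source))
    except SwprofileError:
        raise
    except ValueError as exc:
        raise SequenceFormatError(f"malformed {fmt} input: {exc}") from exc
    return records


def write_fasta(records, path_or_handle) -> None:
    own = not hasattr(path_or_handle, "write")
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.residues}\n")
    finally:
        if own:
            handle.close()


def write_fastq(records, path_or_handle, quality_char: str = "I") -> None:
    """Write records as FASTQ with a uniform placeholder quality."""
    own = not hasattr(path_or_handle, "write")
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        for rec in records:
            handle.write(
                f"@{rec.id}\n{rec.residues}\n+\n{quality_char * len(rec.residues)}\n"
            )
    finally:
        if own:
            handle.close()


def reverse_complement(record: SequenceRecord) -> SequenceRecord:
    """Reverse-complement a DNA/RNA record (A<->T/U, C<->G, N<->N).

    The returned id carries an ``_rc`` suffix to mark orientation; applying
    the operation twice restores the original record (suffix stripped).
    """
    bad = set(record.residues) - _NUCLEOTIDES
    if bad:
        raise ParameterError(
            f"reverse complement is only defined for nucleotide sequences; "
            f"{record.id!r} contains {sorted(bad)}"
        )
    rc = str(Seq(record.residues).reverse_complement())
    if record.residues and "U" in record.residues.upper() and "T" not in record.residues.upper():
        rc = rc.replace("T", "U").replace("t", "u")
    new_id = record.id[:-3] if record.id.endswith("_rc") else record.id + "_rc"
    return SequenceRecord(new_id, rc, record.source)


def build_batch(
    queries: list[SequenceRecord],
    targets: list[SequenceRecord],
    pad_symbol: str = DEFAULT_PAD,
) -> BatchLayout:
    """Assemble a padded batch; N and M are the maxima of actual lengths."""
    if not queries or not targets:
        raise ParameterError("queries and targets must be non-empty")
    if len(pad_symbol) != 1:
        raise ParameterError("pad symbol must be a single character")
    for rec in list(queries) + list(targets):
        if pad_symbol in rec.residues:
            raise ParameterError(
                f"pad symbol {pad_symbol!r} occurs in sequence {rec.id!r}"
            )
    N = max(len(q) for q in queries)
    M = max(len(t) for t in targets)
    return BatchLayout(tuple(queries), tuple(targets), pad_symbol, N, M)


def count_alignment_jobs(X: int, P: int, both_strands: bool = True) -> int:
    """Number of pairwise alignments for X queries vs P targets.

    Searching both strands doubles the count (each target is also aligned
    in reverse complement).
    """
    if X <= 0 or P <= 0:
        raise ParameterError("counts must be positive")
    return X * P * (2 if both_strands else 1)


def iter_sub_batches(layout: BatchLayout, max_cells: int | None = None):
    """Split a batch into query sub-batches of at most ``max_cells`` DP
    cells (X*N*Y*M) each, mirroring a device memory budget.  Results are
    unaffected by the split because alignment is padding- and
    composition-invariant."""
    if max_cells is None:
        yield layout
        return
    per_query = layout.N * layout.Y * layout.M
    chunk = max(1, max_cells // per_query)
    for i in range(0, layout.X, chunk):
        yield BatchLayout(
            layout.queries[i : i + chunk],
            layout.targets,
            layout.pad_symbol,
            layout.N,
            layout.M,
        )
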