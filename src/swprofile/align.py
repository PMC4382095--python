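"""Batch alignment driver: every query x target pair, optionally both strands.

Reverse-strand search aligns each query against the reverse complement of
the target; reported hits carry ``strand='-'`` with target coordinates
mapped back to the forward strand (``t_start = M - rc_end + 1``), so
downstream consumers always see forward-strand target positions.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .engine import fill_blocked
from .profiles import Hit, extract_hits
from .scoring import ScoringScheme, default_dna_scheme
from .seqio import BatchLayout, SequenceRecord, build_batch, reverse_complement


def align_pair(
    query: SequenceRecord,
    target: SequenceRecord,
    scheme: ScoringScheme,
    min_score: float = 20.0,
    max_hits: int = 10,
    both_strands: bool = False,
    block_size: int = 8,
) -> list[Hit]:
    """All qualifying hits for one query x target pair, best score first."""
    state = fill_blocked(query.residues, target.residues, scheme, block_size)
    hits = extract_hits(
        state, scheme, min_score, max_hits,
        query_id=query.id, target_id=target.id, strand="+",
    )
    if both_strands:
        rc = reverse_complement(target)
        state_rc = fill_blocked(query.residues, rc.residues, scheme, block_size)
        m = len(target)
        for h in extract_hits(
            state_rc, scheme, min_score, max_hits,
            query_id=query.id, target_id=target.id, strand="-",
        ):
            h.t_start, h.t_end = m - h.t_end + 1, m - h.t_start + 1
            hits.append(h)
        hits.sort(key=lambda h: -h.score)
        hits = hits[:max_hits]
    return hits


def align_all(
    queries: Iterable[SequenceRecord],
    targets: Iterable[SequenceRecord],
    scheme: ScoringScheme | None = None,
    min_score: float = 20.0,
    max_hits: int = 10,
    both_strands: bool = False,
    block_size: int = 8,
    max_cells: int | None = None,
) -> Iterator[Hit]:
    """Stream hits for every query x target pair of a batch.

    ``max_cells`` caps the DP cells held per sub-batch (a memory budget);
    it never changes any hit.  Hit order across pairs is an implementation
    detail — consumers must key on ids.
    """
    from .seqio import iter_sub_batches

    scheme = scheme or default_dna_scheme()
    layout = build_batch(list(queries), list(targets))
    for sub in iter_sub_batches(layout, max_cells):
        for q in sub.queries:
            for t in sub.targets:
                yield from align_pair(
                    q, t, scheme, min_score, max_hits, both_strands, block_size
                )


def best_hit(hits: Iterable[Hit]) -> Hit | None:
    """Highest-scoring hit; ties broken by (query_id, target_id, strand,
    q_start) for determinism."""
    best = None
    for h in hits:
        if best is None or (-h.score, h.query_id, h.target_id, h.strand, h.q_start) < (
            -best.score, best.query_id, best.target_id, best.strand, best.q_start
        ):
            best = h
    return best
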