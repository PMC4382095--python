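"""Multi-hit traceback and alignment-profile rendering (phases 2 and 3).

Phase 2 scans a filled score matrix for traceback start points — cells whose
value meets a user minimum — and traces each path backwards through the
direction matrix, negating every visited cell's score in place.  Because all
scores are non-negative before traceback, the sign bit is a free marker:
a later trace that reaches a negated cell knows the remainder of that path
already belongs to a better hit and stops there, so the hits reported for
one pair never share a matrix cell.  This yields multiple disjoint local
alignments per pair (best first) from a single reverse pass, without the
matrix recomputation of Waterman-Eggert style iteration; secondary hits that
would share cells with a better hit are truncated at the collision or
dropped entirely if their start cell was already consumed.

Phase 3 renders each traced path into a :class:`Hit`: coordinates, score,
relative score (score / alignment columns), match/mismatch/gap counts and
the three profile strings — aligned query, midline (``|`` match, ``.``
mismatch, ``-`` gap), aligned target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import AlignmentPairState, Direction
from .errors import ParameterError
from .scoring import ScoringScheme

#: Relative-score bin labels, most specific first.
BIN_FULL = "full primer recovery"
BIN_PERFECT = "perfect alignment"
BIN_SOME = "some gaps/mismatches"
BIN_LOW = "low quality"
BIN_VERY_LOW = "very low quality"

#: Bin bounds as fractions of the scheme's match score.  At the default
#: match score of 5.0 these give the printed bounds 5.0 / 4.0 / 3.0.
_SOME_FRACTION = 0.8
_LOW_FRACTION = 0.6

TSV_COLUMNS = [
    "query_id", "target_id", "strand", "score", "relative_score",
    "q_start", "q_end", "t_start", "t_end",
    "matches", "mismatches", "gaps", "length",
    "aligned_query", "midline", "aligned_target",
]


@dataclass(frozen=True)
class StartPoint:
    """A traceback origin: cell coordinates, its score and the direction
    the score came from (left, up or upper-left neighbour)."""

    row: int
    col: int
    score: float
    incoming: Direction


@dataclass
class Hit:
    """One local alignment with its full profile.

    Coordinates are 1-based inclusive on the unpadded forward-strand
    sequences; a reverse-strand hit carries ``strand='-'`` with
    forward-strand target coordinates.  Invariants: ``matches + mismatches
    + gaps == length``; the three profile strings have equal length; the
    score recomputed column-by-column from the profile equals ``score``.
    """

    query_id: str
    target_id: str
    strand: str
    score: float
    relative_score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    mismatches: int
    gaps: int
    length: int
    aligned_query: str
    midline: str
    aligned_target: str

    def to_tsv_row(self) -> str:
        vals = [getattr(self, c) for c in TSV_COLUMNS]
        return "\t".join(
            f"{v:g}" if isinstance(v, float) else str(v) for v in vals
        )


def find_start_points(state: AlignmentPairState, min_score: float) -> list[StartPoint]:
    """Cells qualifying as traceback origins, best score first.

    A cell qualifies when its score is at least ``min_score`` and it is not
    merely the shoulder of a longer alignment — i.e. its diagonal successor
    does not extend it to a strictly greater score via a DIAG step.  Order:
    descending score, ties by (row, col) ascending.
    """
    if not min_score > 0:
        raise ParameterError("min_score must be positive")
    H, D = state.score, state.directions
    qualifies = H >= min_score
    qualifies[0, :] = qualifies[:, 0] = False
    # shoulder suppression: drop cells whose diagonal successor extends
    # them to a strictly greater score via a DIAG step
    shoulder = np.zeros_like(qualifies)
    shoulder[:-1, :-1] = (D[1:, 1:] == Direction.DIAG) & (H[1:, 1:] > H[:-1, :-1])
    qualifies &= ~shoulder
    points = [
        StartPoint(int(i), int(j), float(H[i, j]), Direction(int(D[i, j])))
        for i, j in np.argwhere(qualifies)
    ]
    points.sort(key=lambda p: (-p.score, p.row, p.col))
    return points


def traceback(
    state: AlignmentPairState, start: StartPoint
) -> list[tuple[int, int, Direction]]:
    """Trace one path from ``start``, negating visited scores in place.

    Follows the direction matrix until a STOP cell or an already-negated
    (previously traced) cell is reached; the negated cell acts like STOP,
    truncating the path at the collision so hits stay cell-disjoint.
    Returns the visited cells bottom-right to top-left, or an empty list if
    the start cell itself was consumed by an earlier trace.
    """
    H, D = state.score, state.directions
    n1, m1 = H.shape
    i, j = start.row, start.col
    if not (1 <= i < n1 and 1 <= j < m1):
        raise ParameterError(f"start ({i}, {j}) outside matrix")
    if H[i, j] < 0:
        return []  # start already consumed by an earlier trace
    path: list[tuple[int, int, Direction]] = []
    while True:
        d = Direction(int(D[i, j]))
        if d == Direction.STOP or H[i, j] < 0:
            break
        path.append((i, j, d))
        if H[i, j] > 0:
            H[i, j] = -H[i, j]
        if d == Direction.DIAG:
            i, j = i - 1, j - 1
        elif d == Direction.UP:
            i -= 1
        else:
            j -= 1
    return path


def build_profile(
    path: list[tuple[int, int, Direction]],
    query: str,
    target: str,
    scheme: ScoringScheme,
    query_id: str = "query",
    target_id: str = "target",
    strand: str = "+",
) -> Hit:
    """Render a traced path into a :class:`Hit` (phase 3).

    DIAG columns pair residues (``|`` when equal, ``.`` otherwise); an UP
    step consumes a query residue over a target gap; a LEFT step a target
    residue over a query gap.  The score is accumulated column-by-column
    from the scheme so it always equals what the profile shows.
    """
    if not path:
        raise ParameterError("empty path")
    aq, mid, at = [], [], []
    matches = mismatches = gaps = 0
    score = 0.0
    prev = None
    for i, j, d in reversed(path):  # top-left to bottom-right
        if prev is not None:
            pi, pj = prev
            if not (i - pi in (0, 1) and j - pj in (0, 1) and (i, j) != prev):
                raise ParameterError(f"non-adjacent path step ({pi},{pj})->({i},{j})")
        prev = (i, j)
        if d == Direction.DIAG:
            qc, tc = query[i - 1], target[j - 1]
            aq.append(qc)
            at.append(tc)
            if qc == tc:
                mid.append("|")
                matches += 1
            else:
                mid.append(".")
                mismatches += 1
            score += scheme.substitution(qc, tc)
        elif d == Direction.UP:
            aq.append(query[i - 1])
            at.append("-")
            mid.append("-")
            gaps += 1
            score += scheme.gap_penalty
        elif d == Direction.LEFT:
            aq.append("-")
            at.append(target[j - 1])
            mid.append("-")
            gaps += 1
            score += scheme.gap_penalty
        else:
            raise ParameterError("STOP direction inside path")
    q_rows = [i for i, _, d in path if d in (Direction.DIAG, Direction.UP)]
    t_cols = [j for _, j, d in path if d in (Direction.DIAG, Direction.LEFT)]
    length = len(path)
    return Hit(
        query_id=query_id,
        target_id=target_id,
        strand=strand,
        score=score,
        relative_score=score / length,
        q_start=min(q_rows) if q_rows else path[-1][0],
        q_end=max(q_rows) if q_rows else path[-1][0],
        t_start=min(t_cols) if t_cols else path[-1][1],
        t_end=max(t_cols) if t_cols else path[-1][1],
        matches=matches,
        mismatches=mismatches,
        gaps=gaps,
        length=length,
        aligned_query="".join(aq),
        midline="".join(mid),
        aligned_target="".join(at),
    )


def extract_hits(
    state: AlignmentPairState,
    scheme: ScoringScheme,
    min_score: float = 20.0,
    max_hits: int = 10,
    query_id: str = "query",
    target_id: str = "target",
    strand: str = "+",
) -> list[Hit]:
    """Trace up to ``max_hits`` cell-disjoint local alignments, best first.

    Start points are processed in descending score order; a start consumed
    by an earlier trace yields nothing, and a path truncated by collision
    with an earlier trace is kept only if the surviving alignment still
    scores at least ``min_score`` — otherwise it is a sub-threshold remnant
    of a better hit and is discarded.  With ``max_hits=1`` this reduces to
    the classic single best local alignment.
    """
    if max_hits < 1:
        raise ParameterError("max_hits must be >= 1")
    hits: list[Hit] = []
    for sp in find_start_points(state, min_score):
        if len(hits) >= max_hits:
            break
        path = traceback(state, sp)
        if not path:
            continue
        hit = build_profile(
            path, state.query, state.target, scheme,
            query_id=query_id, target_id=target_id, strand=strand,
        )
        if hit.score >= min_score:
            hits.append(hit)
    hits.sort(key=lambda h: -h.score)
    return hits


def classify_relative_score(
    r: float,
    full_span: bool = False,
    match_score: float = 5.0,
    atol: float = 1e-9,
) -> str:
    """Quality bin for a relative score (score per alignment column).

    A relative score equal to the match score means every column is a
    match; with full target coverage that is a full primer recovery,
    otherwise a perfect (but partial) alignment.  Below that, half-open
    bins at 0.8x and 0.6x the match score (4.0 and 3.0 at the default
    match score of 5.0) grade alignment quality.
    """
    if r < 0:
        raise ParameterError("relative score must be non-negative")
    if r >= match_score - atol:
        return BIN_FULL if full_span else BIN_PERFECT
    if r >= _SOME_FRACTION * match_score:
        return BIN_SOME
    if r >= _LOW_FRACTION * match_score:
        return BIN_LOW
    return BIN_VERY_LOW


def write_hits_tsv(hits, path_or_handle) -> None:
    """Write hits as TSV, one row per hit, header first.

    Row order across pairs carries no meaning; consumers must key on the
    query/target ids.
    """
    own = not hasattr(path_or_handle, "write")
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        handle.write("\t".join(TSV_COLUMNS) + "\n")
        for h in hits:
            handle.write(h.to_tsv_row() + "\n")
    finally:
        if own:
            handle.close()
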