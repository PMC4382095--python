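"""Score-matrix computation (phase 1 of the aligner).

Two fills of the Smith-Waterman recurrence are provided:

* :func:`fill_naive` — plain row-major double loop in pure Python.  Slow,
  transparent, and used throughout the test suite as the brute-force oracle.
* :func:`fill_blocked` — the production fill.  The (n+1)x(m+1) matrix is
  tiled into 8x8 blocks scheduled along block anti-diagonals (a wavefront:
  every block depends only on its left, upper and upper-left neighbours,
  which lie on strictly smaller anti-diagonals, so all blocks sharing an
  anti-diagonal index are mutually independent).  Cells inside a block are
  likewise evaluated along the block's internal anti-diagonals.  The
  schedule is executed sequentially here, but the dependency structure is
  exactly the one a data-parallel device would exploit, and the output is
  required — and tested — to equal the naive fill cell-for-cell.

Both fills use the recurrence

    H[i,j] = max(0, H[i-1,j-1] + s(q_i, t_j), H[i-1,j] + g, H[i,j-1] + g)

with a direction matrix recording the argmax.  Ties among positive options
break DIAG > UP > LEFT; a best value of 0 always records STOP.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from numba import njit

from .errors import ParameterError
from .scoring import ScoringScheme

BLOCK_SIZE = 8
THREADS_PER_BLOCK = BLOCK_SIZE * BLOCK_SIZE


class Direction(IntEnum):
    STOP = 0
    DIAG = 1
    UP = 2
    LEFT = 3


@dataclass
class AlignmentPairState:
    """Filled DP state for one query x target pair.

    ``score`` and ``directions`` are (n+1) x (m+1); row 0 and column 0 are
    fixed at zero/STOP.  ``max_cell`` is ``(row, col, value)`` of the matrix
    maximum, first occurrence in row-major order.  Rows index the query,
    columns the target.
    """

    query: str
    target: str
    score: np.ndarray
    directions: np.ndarray

    @property
    def max_cell(self) -> tuple[int, int, float]:
        flat = int(np.argmax(self.score))
        r, c = divmod(flat, self.score.shape[1])
        return (r, c, float(self.score[r, c]))


@dataclass(frozen=True)
class BlockGrid:
    """Tiling of an n x m cell matrix into ``block_size`` square blocks."""

    n: int
    m: int
    block_size: int = BLOCK_SIZE

    @property
    def blocks_x(self) -> int:
        return -(-self.n // self.block_size)

    @property
    def blocks_y(self) -> int:
        return -(-self.m // self.block_size)

    def wavefront(self) -> list[list[tuple[int, int]]]:
        """Blocks grouped by anti-diagonal index ``bx + by``.

        Every block's upstream neighbours lie on strictly smaller
        anti-diagonals, so each group is mutually independent.
        """
        nbx, nby = self.blocks_x, self.blocks_y
        waves = []
        for w in range(nbx + nby - 1):
            wave = [
                (bx, w - bx)
                for bx in range(min(w, nbx - 1), max(0, w - nby + 1) - 1, -1)
            ]
            waves.append(wave)
        return waves


def _strip_pad(seq: str, pad: str | None) -> str:
    return seq.rstrip(pad) if pad else seq


def fill_naive(
    query: str,
    target: str,
    scheme: ScoringScheme,
    pad_symbol: str | None = None,
) -> AlignmentPairState:
    """Reference fill: row-major, top-left to bottom-right.

    Serves as the brute-force oracle for the blocked fill; every cell is
    evaluated only after its upper, left and upper-left neighbours.
    """
    query = _strip_pad(query, pad_symbol)
    target = _strip_pad(target, pad_symbol)
    if not query or not target:
        raise ParameterError("query and target must be non-empty after unpadding")
    q = scheme.encode(query)
    t = scheme.encode(target)
    sub = scheme.matrix
    gap = scheme.gap_penalty
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    D = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s_diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            s_up = H[i - 1, j] + gap
            s_left = H[i, j - 1] + gap
            best, d = s_diag, Direction.DIAG
            if s_up > best:
                best, d = s_up, Direction.UP
            if s_left > best:
                best, d = s_left, Direction.LEFT
            if best <= 0.0:
                best, d = 0.0, Direction.STOP
            H[i, j] = best
            D[i, j] = d
    return AlignmentPairState(query, target, H, D)


@njit(cache=False)
def _blocked_kernel(q, t, sub, gap, block):  # pragma: no cover - numba
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    D = np.zeros((n + 1, m + 1), dtype=np.int8)
    nbx = (n + block - 1) // block
    nby = (m + block - 1) // block
    for w in range(nbx + nby - 1):
        bx_hi = min(w, nbx - 1)
        bx_lo = max(0, w - nby + 1)
        for bx in range(bx_hi, bx_lo - 1, -1):
            by = w - bx
            i0 = bx * block
            j0 = by * block
            ilim = min(block, n - i0)
            jlim = min(block, m - j0)
            for d in range(ilim + jlim - 1):
                di_hi = min(d, ilim - 1)
                di_lo = max(0, d - jlim + 1)
                for di in range(di_lo, di_hi + 1):
                    dj = d - di
                    i = i0 + di + 1
                    j = j0 + dj + 1
                    s_diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
                    s_up = H[i - 1, j] + gap
                    s_left = H[i, j - 1] + gap
                    best = s_diag
                    bdir = 1
                    if s_up > best:
                        best = s_up
                        bdir = 2
                    if s_left > best:
                        best = s_left
                        bdir = 3
                    if best <= 0.0:
                        best = 0.0
                        bdir = 0
                    H[i, j] = best
                    D[i, j] = bdir
    return H, D


def fill_blocked(
    query: str,
    target: str,
    scheme: ScoringScheme,
    block_size: int = BLOCK_SIZE,
    pad_symbol: str | None = None,
) -> AlignmentPairState:
    """Production fill: 8x8-block anti-diagonal wavefront schedule.

    Blocks are visited in wavefront order; cells within a block along the
    block's internal anti-diagonals.  Neighbour values missing at a block's
    boundary (first block row/column) are zeros, exactly as in the naive
    fill's initialisation.  Output is cell-for-cell identical to
    :func:`fill_naive`.
    """
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    query = _strip_pad(query, pad_symbol)
    target = _strip_pad(target, pad_symbol)
    if not query or not target:
        raise ParameterError("query and target must be non-empty after unpadding")
    q = scheme.encode(query)
    t = scheme.encode(target)
    H, D = _blocked_kernel(q, t, scheme.matrix, scheme.gap_penalty, block_size)
    return AlignmentPairState(query, target, H, D)


def max_block_count(X: int, N: int, Y: int, M: int) -> int:
    """Upper bound on 64-thread blocks for a full batch: (X*N*Y*M) / 64.

    Every query x target pair contributes an N x M cell matrix tiled into
    8x8 blocks, so at most X*N*Y*M cells / 64 cells-per-block blocks exist.
    Lengths should be the padded (batch) lengths; non-multiples of 8 are
    rounded as exact division of the cell count.
    """
    for name, v in (("X", X), ("N", N), ("Y", Y), ("M", M)):
        if v <= 0:
            raise ParameterError(f"{name} must be positive")
    return (X * N * Y * M) // THREADS_PER_BLOCK


def initial_block_count(X: int, Y: int) -> int:
    """Blocks active at batch start: one top-left block per pair, X*Y."""
    if X <= 0 or Y <= 0:
        raise ParameterError("X and Y must be positive")
    return X * Y
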