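# Methods

## Alignment model

`swprofile` computes Smith–Waterman local alignments under a symmetric
substitution matrix and a **linear** gap model: every gapped alignment
column costs the same penalty `g < 0`. There is no gap-open/gap-extend
distinction; affine gaps, codon-aware indel scoring and semi-global modes
are out of scope. Scores are real-valued; integer-valued schemes are
recommended when bitwise agreement between execution schedules matters
(all defaults are integers).

Default nucleotide scores are match **+5.0**, mismatch **−3.0**, gap
**−8.0** over the alphabet `{A,C,G,T,U,N}`. The match score of 5 anchors
the relative-score scale (below); the mismatch and gap magnitudes follow
the ratios of common DNA schemes scaled to that match score and are plain
parameters, not fitted quantities. `N` and any other symbol outside
`{A,C,G,T,U}` score as a mismatch against everything, including
themselves — the simplest conservative treatment of ambiguity codes.
Protein/RNA scoring uses NCBI-format matrix files (parsed via Biopython);
the loader rejects asymmetric matrices, and the gap penalty is always
supplied separately because matrix files carry none.

## Execution schedules and why they must agree

Cell `(i,j)` of the DP matrix depends on `(i-1,j)`, `(i,j-1)` and
`(i-1,j-1)`. Two schedules respect that dependency here:

* **naive** — row-major double loop, pure Python; the transparent oracle.
* **blocked** — the matrix is tiled into 8×8-cell blocks; blocks are
  visited by anti-diagonal index `bx+by` (all blocks of one anti-diagonal
  are mutually independent), and cells inside a block are visited along
  the block's internal anti-diagonals. Boundary neighbours missing at the
  first block row/column contribute zeros. The schedule is executed
  sequentially (a numba kernel), but its dependency structure is the one a
  data-parallel device with 64-thread blocks would exploit.

The blocked fill is contractually **identical** to the naive fill —
scores, directions and maximum cell — and the test suite enforces this on
hundreds of randomized pairs plus a derandomized property test. The
intra-block visit order is otherwise unconstrained: any order respecting
the cell dependencies gives the same output, which is the invariant that
matters. Argmax ties in the recurrence break DIAG > UP > LEFT, applied
identically in both fills; a best value of 0 always records STOP. The
matrix maximum is reported as its first row-major occurrence so both fills
agree on ties.

Batches pad X queries to the longest query length N and Y targets to M
with a reserved symbol (`#` by default) that is outside every scoring
alphabet. Padding is a layout device only: each pair's DP runs over true
lengths, so results are invariant to padding and to batch composition
(tested). N and M are computed per batch as maxima of the actual lengths —
minimal padding with no user input. `--batch-cells` splits large runs into
query sub-batches under a DP-cell budget, mirroring a device memory limit;
by the same invariance it cannot change any hit.

## Multi-hit traceback

Start points are cells with score ≥ `min_score` (default 20.0 — four
matches at the default match score), excluding cells whose diagonal
successor extends them to a strictly greater score ("shoulders" of a
longer alignment). Starts are processed in descending score order, ties by
(row, col). Tracing negates each visited cell's score in place — scores
are non-negative before traceback, so the sign is a free marker — and a
path that reaches a negated cell terminates there, as if at STOP. A start
whose own cell was already negated yields nothing. Consequences, all
deliberate:

* hits of one pair are pairwise cell-disjoint, best hit first;
* there is **no rescoring pass** after masking (unlike Waterman–Eggert
  iteration): a secondary alignment that shares cells with a better hit is
  truncated at the collision or dropped;
* a truncated remnant is kept only if the surviving columns still score
  ≥ `min_score`; otherwise it is discarded as debris of the better hit.

Each path is rendered into a hit whose score is accumulated
column-by-column from the scheme, so the reported score always equals the
profile's score (conservation is asserted for every hit in the test runs).
Coordinates are 1-based inclusive on the unpadded forward strand;
reverse-strand search aligns the query against the reverse-complemented
target and maps target coordinates back to the forward strand with
`strand='-'`.

The **relative score** is score / alignment columns, where columns include
gap columns — the natural reading of "alignment length" for a profile.
Quality bins are half-open, with the exact-maximum case split by target
coverage: relative = match score and full target span → *full primer
recovery*; relative = match score otherwise → *perfect alignment*; then
[0.8, 1.0) of the match score → *some gaps/mismatches*, [0.6, 0.8) →
*low quality*, below → *very low quality*. At match = 5 these bounds are
5.0 / 4.0 / 3.0. Expressing them as fractions keeps the bins meaningful
under non-default schemes. In bin summaries the full-recovery row is a
subset of the perfect row; the perfect/some/low/very-low rows partition
the hits and sum to 100%.

## Synthetic data

The tagged-read generator emulates a pyrosequencing amplicon design:

```
[5-nt ID tag][5' primer][random genomic insert][rc(5' primer)][rc(tag)]
```

Defaults: two alternative 5' primers of 19 and 21 nt (adapter-style fixed
sequences), 28 distinct 5-nt tags spaced through the 4^5 possible 5-mers,
genomic inserts of 10–548 nt (error-free reads span ~60–600 nt, a typical
pyrosequencing length range), and a per-base error rate of 1% — the
error level of that platform class — applied uniformly as substitution,
insertion or deletion with equal probability. The 3' structure is the
reverse complement of the 5' structure, so a read looks the same from
either strand (as in a two-ended amplicon design); an optional fraction of
reads is emitted reverse-complemented. Generation is deterministic given a
seed.

What the generator does **not** emulate: position-dependent error rates,
homopolymer-specific indels (the dominant real pyrosequencing artifact),
quality-score structure, chimeras, or sample-size imbalance between tags.
Passing the recovery tests therefore shows the pipeline recovers planted
structure under uniform noise, not that it reproduces any particular real
run's recovery percentage.

The isotype references are **synthetic stand-ins** (labelled as such in
code): one random 32-nt IgE constant-region segment and six 76-nt IgG
sub-type segments derived from a common random sequence with three
sub-type-specific substitutions each, mimicking the short lengths and the
high mutual similarity of real IgG sub-types. Reads are drawn from a
reference, mutated per base, and half are reverse-complemented.

## Pipelines

**Tag recovery.** Each read is aligned to every 5' primer on both strands;
the single best hit (multi-hit aware, so an intact primer copy always
beats a degraded one) fixes the primer position, and the tag is the five
bases immediately 5' of the hit — reverse-complemented for minus-strand
hits. No tag is reported when no hit reaches `min_score` or fewer than
five bases precede the primer. Every hit is binned by relative score.

**Isotype assignment.** Each read is aligned to all labelled references on
both strands; the call is the class of the single best hit if it reaches
`min_score`, with cross-class score ties left *unclassified* (the
conservative choice; no tie rule is defensible from first principles).
The mutation load of a call is mismatches + gaps of the best alignment —
the only hit-level quantity that matches the term. Note that the default
`min_score` of 20 confirms reads that genuinely resemble a reference;
rejecting arbitrary unrelated sequences needs a far higher threshold,
since chance local alignments of a random 40-mer against 76-nt references
reach scores around 90 (the class-separation test uses 120).

## Problem sizes and numerics

The test suite runs the oracle-equivalence check on 500 random pairs of
lengths 1–64 under three schemes, best-hit agreement against an
independent local aligner (Biopython's `PairwiseAligner`) on 200 pairs,
and pipeline recovery on 1000 synthetic reads per case — sizes chosen so
the whole suite completes in a couple of minutes on one CPU while still
exercising every block-boundary case. Scores are float64 throughout;
with integer-valued schemes all DP arithmetic is exact, which is what
makes "bitwise equality" between the two fills and exact profile rescoring
meaningful. Relative-score equality at the bin edges uses a 1e-9
tolerance; the perfect-match ratio `(5L)/L` is exact in float64 anyway.

## Known limitations

* Linear gaps only; no affine model, no SAM output, no quality-aware
  scoring.
* No Waterman–Eggert rescoring: secondary hits overlapping a better hit
  are truncated or dropped rather than re-optimised around it.
* The wavefront schedule is sequential; the package demonstrates and
  tests the schedule's correctness, not device-level speed.
* Relative-score bins assume the scheme's match score is the natural
  score ceiling per column; schemes whose off-diagonal values exceed the
  diagonal would make the bins meaningless (the loader does not forbid
  them, matrix files being user-supplied).
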