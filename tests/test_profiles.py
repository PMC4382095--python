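import pytest

from swprofile import (
    ParameterError,
    build_profile,
    classify_relative_score,
    default_dna_scheme,
    extract_hits,
    fill_naive,
    find_start_points,
    traceback,
    write_hits_tsv,
)
from swprofile.profiles import (
    BIN_FULL,
    BIN_LOW,
    BIN_PERFECT,
    BIN_SOME,
    BIN_VERY_LOW,
    TSV_COLUMNS,
)
from .conftest import random_dna


def recompute_score(hit, scheme):
    """Column-by-column rescore of a hit from its profile strings."""
    total = 0.0
    for qc, tc in zip(hit.aligned_query, hit.aligned_target):
        total += scheme.gap_penalty if "-" in (qc, tc) else scheme.substitution(qc, tc)
    return total


class TestStartPoints:
    def test_all_zero_matrix_yields_nothing(self, dna_scheme):
        state = fill_naive("AAAA", "GGGG", dna_scheme)
        assert find_start_points(state, 1.0) == []

    def test_self_alignment_has_unique_maximum_start(self, dna_scheme):
        state = fill_naive("ACGT", "ACGT", dna_scheme)
        pts = find_start_points(state, 20.0)
        assert [(p.row, p.col, p.score) for p in pts] == [(4, 4, 20.0)]

    def test_two_copies_give_two_starts(self, dna_scheme):
        # hand-enumerated: both ACGT copies reach score 20; every interior
        # diagonal shoulder is suppressed
        state = fill_naive("ACGTTTTTACGT", "ACGT", dna_scheme)
        pts = find_start_points(state, 20.0)
        assert [(p.row, p.col, p.score) for p in pts] == [
            (4, 4, 20.0),
            (12, 4, 20.0),
        ]

    def test_ordered_by_descending_score_then_position(self, dna_scheme, rng):
        state = fill_naive(random_dna(rng, 50), random_dna(rng, 30), dna_scheme)
        pts = find_start_points(state, 5.0)
        keys = [(-p.score, p.row, p.col) for p in pts]
        assert keys == sorted(keys)


class TestTraceback:
    def test_identical_sequences_trace_full_diagonal(self, dna_scheme):
        state = fill_naive("ACGTAC", "ACGTAC", dna_scheme)
        (start,) = find_start_points(state, 30.0)
        path = traceback(state, start)
        assert len(path) == 6
        assert all(d == 1 for _, _, d in path)

    def test_visited_cells_negated_and_rerun_is_empty(self, dna_scheme):
        state = fill_naive("ACGT", "ACGT", dna_scheme)
        (start,) = find_start_points(state, 20.0)
        path = traceback(state, start)
        assert all(state.score[i, j] < 0 for i, j, _ in path)
        assert traceback(state, start) == []

    def test_two_hit_paths_are_disjoint(self, dna_scheme):
        state = fill_naive("ACGTTTTTACGT", "ACGT", dna_scheme)
        p1, p2 = [traceback(state, s) for s in find_start_points(state, 20.0)]
        assert len(p1) == len(p2) == 4
        assert not {(i, j) for i, j, _ in p1} & {(i, j) for i, j, _ in p2}

    def test_out_of_matrix_start_rejected(self, dna_scheme):
        from swprofile import StartPoint, Direction

        state = fill_naive("ACGT", "ACGT", dna_scheme)
        with pytest.raises(ParameterError):
            traceback(state, StartPoint(9, 9, 1.0, Direction.DIAG))


class TestBuildProfile:
    def test_perfect_self_alignment_profile(self, dna_scheme):
        state = fill_naive("ACGT", "ACGT", dna_scheme)
        (hit,) = extract_hits(state, dna_scheme, min_score=20.0)
        assert hit.midline == "||||"
        assert (hit.matches, hit.mismatches, hit.gaps) == (4, 0, 0)
        assert hit.relative_score == 5.0

    def test_single_mismatch_profile(self, dna_scheme):
        state = fill_naive("ACGT", "AGGT", dna_scheme)
        (hit,) = extract_hits(state, dna_scheme, min_score=12.0)
        assert hit.midline == "|.||"
        assert (hit.matches, hit.mismatches) == (3, 1)
        assert hit.score == 12.0

    def test_gapped_profile_counts_mutations(self, dna_scheme):
        # query lacks two bases of the target and has one substitution:
        # the profile shows two gaps and one mismatch => 3 mutations
        target = "CAGCCCTGCTTTATACCATGTCAC"
        query = "CAGCACTGTTTATACATGTCAC"  # sub at 5, deletions at 9 and 17
        state = fill_naive(query, target, dna_scheme)
        (hit,) = extract_hits(state, dna_scheme, min_score=20.0, max_hits=1)
        assert hit.gaps == 2 and hit.mismatches == 1
        assert hit.length == 24 and hit.score == 86.0
        assert hit.mismatches + hit.gaps == 3

    def test_profile_faithfulness_and_conservation(self, dna_scheme, rng):
        for _ in range(25):
            q = random_dna(rng, int(rng.integers(10, 60)))
            t = random_dna(rng, int(rng.integers(10, 60)))
            state = fill_naive(q, t, dna_scheme)
            for hit in extract_hits(state, dna_scheme, min_score=10.0, max_hits=5):
                assert hit.matches + hit.mismatches + hit.gaps == hit.length
                assert len(hit.aligned_query) == len(hit.midline) == hit.length
                assert recompute_score(hit, dna_scheme) == hit.score
                assert hit.aligned_query.replace("-", "") in q
                assert hit.aligned_target.replace("-", "") in t

    def test_malformed_path_rejected(self, dna_scheme):
        from swprofile import Direction

        state = fill_naive("ACGT", "ACGT", dna_scheme)
        bad = [(4, 4, Direction.DIAG), (1, 1, Direction.DIAG)]
        with pytest.raises(ParameterError):
            build_profile(bad, state.query, state.target, dna_scheme)


class TestExtractHits:
    def test_single_hit_equals_matrix_maximum(self, dna_scheme, rng):
        q, t = random_dna(rng, 40), random_dna(rng, 40)
        state = fill_naive(q, t, dna_scheme)
        best = state.max_cell[2]
        if best >= 10.0:
            (hit,) = extract_hits(state, dna_scheme, min_score=10.0, max_hits=1)
            assert hit.score == best

    def test_degraded_and_intact_copy_ranked_by_score(self, dna_scheme):
        # low-self-similarity primer so no incidental secondary hits occur
        primer = "CCATGAGGATTTAACCGCGGC"
        degraded = primer[:10]  # truncated copy, score 50
        read = "AG" + degraded + "C" + "GATTC" + primer + "ACGTACGT"
        state = fill_naive(read, primer, dna_scheme)
        hits = extract_hits(state, dna_scheme, min_score=20.0)
        assert len(hits) == 2
        assert hits[0].score > hits[1].score
        assert hits[0].q_start == 19  # intact copy starts at read position 19
        cells = [
            (h.q_start, h.q_end) for h in hits
        ]
        assert cells[0][0] > cells[1][1]  # disjoint read intervals

    def test_score_monotone_and_disjoint_across_hits(self, dna_scheme, rng):
        q = random_dna(rng, 80)
        t = random_dna(rng, 25)
        state = fill_naive(q, t, dna_scheme)
        hits = extract_hits(state, dna_scheme, min_score=8.0, max_hits=10)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_min_score_above_maximum_yields_nothing(self, dna_scheme):
        state = fill_naive("ACGT", "ACGT", dna_scheme)
        assert extract_hits(state, dna_scheme, min_score=100.0) == []

    def test_determinism(self, dna_scheme, rng):
        q, t = random_dna(rng, 60), random_dna(rng, 30)
        runs = [
            extract_hits(fill_naive(q, t, dna_scheme), dna_scheme, 8.0, 10)
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_invalid_max_hits(self, dna_scheme):
        state = fill_naive("ACGT", "ACGT", dna_scheme)
        with pytest.raises(ParameterError):
            extract_hits(state, dna_scheme, min_score=5.0, max_hits=0)


class TestRelativeScoreBins:
    @pytest.mark.parametrize(
        "r,full_span,expected",
        [
            (5.0, True, BIN_FULL),
            (5.0, False, BIN_PERFECT),
            ((20 * 5 - 3) / 21, False, BIN_SOME),  # one mismatch in 21 columns
            (4.0, False, BIN_SOME),
            (3.5, False, BIN_LOW),
            (3.0, False, BIN_LOW),
            (2.99, False, BIN_VERY_LOW),
            (0.0, False, BIN_VERY_LOW),
        ],
    )
    def test_bin_assignment(self, r, full_span, expected):
        assert classify_relative_score(r, full_span) == expected

    def test_negative_score_rejected(self):
        with pytest.raises(ParameterError):
            classify_relative_score(-0.1)


def test_tsv_writer_columns_and_rows(tmp_path, dna_scheme):
    state = fill_naive("ACGTACGT", "ACGTACGT", dna_scheme)
    hits = extract_hits(state, dna_scheme, min_score=20.0)
    out = tmp_path / "hits.tsv"
    write_hits_tsv(hits, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == TSV_COLUMNS
    assert len(lines) == 1 + len(hits)
    row = dict(zip(TSV_COLUMNS, lines[1].split("\t")))
    assert row["midline"] == "||||||||"
    assert float(row["relative_score"]) == 5.0
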