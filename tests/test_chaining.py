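"""Step-1 chaining: diagonals, entry/exit point sets, the dynamic program,
and rendering of traversals — checked against exhaustive brute-force oracles."""

from __future__ import annotations

import random

import pytest

from oracles import (
    best_traversal_score,
    brute_force_mems,
    brute_force_points,
    nw_semiglobal_plain,
)

from novograph.chaining import (
    NoAlignmentError,
    ORIGIN,
    PathPoint,
    TERMINUS,
    build_point_sets,
    chain,
    find_diagonals,
    global_align_contig,
    make_diagonal,
    maximal_exact_matches,
    transition_score,
    traversal_to_alignment,
    validate_traversal,
)
from novograph.io import LocalAlignmentRecord, SequenceRecord, revcomp, ungapped
from novograph.synth import generate_reference, nw_semiglobal_oracle

from conftest import gapless_record


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mem_diagonals(ref_seq, contig_seq, k):
    """Gapless diagonals from the brute-force MEM oracle."""
    recs = [
        gapless_record("chr1", "c", ref_seq, j, i, L)
        for j, i, L in brute_force_mems(ref_seq, contig_seq, k)
    ]
    return [make_diagonal(r, diag_id=f"d{n}") for n, r in enumerate(recs)]


# ---------------------------------------------------------------------------
# diagonals
# ---------------------------------------------------------------------------

class TestMakeDiagonal:
    def test_endpoint_convention(self):
        # alignment between reference positions 4..10 and contig positions 3..11
        rec = LocalAlignmentRecord(
            contig_id="c", ref_id="r", strand="+",
            ref_start=4, ref_end=10, contig_start=3, contig_end=11,
            aligned_ref="AC-GT-CAG", aligned_contig="ACTGTACAG", score=5,
        )
        d = make_diagonal(rec)
        assert (d.d1, d.d2, d.d3, d.d4) == (4, 3, 10, 11)
        assert d.entry_state(0) == (3, 2)
        assert d.exit_state(d.n_columns - 1) == (10, 11)

    def test_prefix_scores_all_match(self):
        rec = gapless_record("r", "c", "ACGTT", 0, 0, 5)
        assert list(make_diagonal(rec).prefix) == [1, 2, 3, 4, 5]

    def test_prefix_scores_with_mismatch(self):
        rec = LocalAlignmentRecord(
            contig_id="c", ref_id="r", strand="+",
            ref_start=1, ref_end=4, contig_start=1, contig_end=4,
            aligned_ref="ACGT", aligned_contig="ACCT", score=2,
        )
        assert list(make_diagonal(rec).prefix) == [1, 2, 1, 2]


# ---------------------------------------------------------------------------
# entry / exit points
# ---------------------------------------------------------------------------

class TestPointSets:
    def test_single_diagonal_has_no_within_points(self):
        d = make_diagonal(gapless_record("r", "c", "ACGTACGT", 2, 0, 6), "d0")
        entries, exits = build_point_sets([d])
        assert [(p.kind, p.state) for p in entries] == [("ENTRY_START", (2, 0))]
        assert [(p.kind, p.state) for p in exits] == [("EXIT_END", (8, 6))]

    def test_mixed_strand_rejected(self):
        ref = "ACGTACGTAC"
        a = make_diagonal(gapless_record("r", "c", ref, 0, 0, 5, "+"), "a")
        b = make_diagonal(gapless_record("r", "c", ref, 0, 0, 5, "-"), "b")
        with pytest.raises(ValueError):
            build_point_sets([a, b])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_iff_condition(self, seed):
        """Point sets equal direct enumeration of the printed iff-condition
        over all columns (disjoint, overlapping, and coordinate-sharing
        diagonals all arise in random MEM instances)."""
        rng = random.Random(1000 + seed)
        ref_seq = random_dna(rng, rng.randint(30, 50))
        contig_seq = random_dna(rng, rng.randint(30, 50))
        diags = mem_diagonals(ref_seq, contig_seq, 4)
        if not diags:
            pytest.skip("no shared 4-mers in this draw")
        entries, exits = build_point_sets(diags)
        oracle_entries, oracle_exits = brute_force_points(diags)
        assert {(p.diagonal_id, p.state) for p in entries} == {
            (d, s) for d, s, _c in oracle_entries
        }
        assert {(p.diagonal_id, p.state) for p in exits} == {
            (d, s) for d, s, _c in oracle_exits
        }


# ---------------------------------------------------------------------------
# transition scoring
# ---------------------------------------------------------------------------

class TestTransitionScore:
    def test_abutting_jump_is_free(self):
        x = PathPoint("a", 10, 11, "EXIT_END", 5)
        e = PathPoint("b", 10, 11, "ENTRY_START", 0)
        assert transition_score(x, e, -1) == 0

    def test_jump_costs_gap_score_per_skipped_base(self):
        x = PathPoint("a", 10, 11, "EXIT_END", 5)
        e = PathPoint("b", 13, 12, "ENTRY_START", 0)
        assert transition_score(x, e, -1) == -4

    def test_origin_jump_free_on_reference_dimension(self):
        origin = PathPoint(None, 0, 0, ORIGIN)
        e = PathPoint("b", 500, 3, "ENTRY_START", 0)
        assert transition_score(origin, e, -1) == -3

    def test_monotonicity_violation_raises(self):
        x = PathPoint("a", 10, 11, "EXIT_END", 5)
        e = PathPoint("b", 9, 12, "ENTRY_START", 0)
        with pytest.raises(ValueError):
            transition_score(x, e, -1)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

class TestChain:
    def test_single_full_coverage_diagonal(self):
        rng = random.Random(0)
        ref_seq = random_dna(rng, 100)
        d = make_diagonal(gapless_record("r", "c", ref_seq, 0, 0, 100), "d0")
        trav = chain([d], 100, 100)
        assert trav.score == 100
        kinds = [p.kind for p in trav.points]
        assert kinds == [ORIGIN, "ENTRY_START", "EXIT_END", TERMINUS]
        validate_traversal(trav, [d], 100, 100)

    def test_two_diagonal_jump_scoring(self):
        # ref 1-40/contig 1-40 and ref 61-100/contig 41-80: 40+40 - (20+0)
        rng = random.Random(1)
        ref_seq = random_dna(rng, 100)
        a = make_diagonal(gapless_record("r", "c", ref_seq, 0, 0, 40), "a")
        b = make_diagonal(gapless_record("r", "c", ref_seq, 60, 40, 40), "b")
        trav = chain([a, b], 100, 80)
        assert trav.score == 60
        validate_traversal(trav, [a, b], 100, 80)

    def test_empty_diagonal_set_signals_no_alignment(self):
        with pytest.raises(NoAlignmentError):
            chain([], 100, 100)

    @pytest.mark.parametrize("seed", range(40))
    def test_optimal_vs_exhaustive_enumeration(self, seed):
        """chain() equals the optimum over exhaustive enumeration of valid
        traversals, and never beats the full semi-global NW oracle."""
        rng = random.Random(2000 + seed)
        n, m = rng.randint(40, 60), rng.randint(40, 60)
        ref_seq = random_dna(rng, n)
        if rng.random() < 0.5:  # related pair: contig from a ref slice
            s = rng.randint(0, n - 30)
            contig_seq = ref_seq[s : s + 30]
            contig_seq = (
                contig_seq[:10] + random_dna(rng, rng.randint(0, 4)) + contig_seq[12:]
            )
            m = len(contig_seq)
        else:
            contig_seq = random_dna(rng, m)
        diags = mem_diagonals(ref_seq, contig_seq, 5)
        if not diags or len(diags) > 8:
            pytest.skip("instance outside the <=8 diagonal regime")
        trav = chain(diags, n, m)
        validate_traversal(trav, diags, n, m)
        assert trav.score == best_traversal_score(diags, n, m)
        assert trav.score <= nw_semiglobal_oracle(ref_seq, contig_seq)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

class TestTraversalToAlignment:
    def test_single_diagonal_round_trip(self):
        rng = random.Random(3)
        ref_seq = random_dna(rng, 50)
        ref = SequenceRecord("r", ref_seq)
        contig = SequenceRecord("c", ref_seq[10:40])
        d = make_diagonal(gapless_record("r", "c", ref_seq, 10, 0, 30), "d0")
        aln = traversal_to_alignment(chain([d], 50, 30), [d], ref, contig)
        assert aln.aligned_ref == aln.aligned_contig == ref_seq[10:40]
        assert (aln.ref_start, aln.ref_end) == (10, 40)

    def test_jump_renders_reference_deletion_block(self):
        rng = random.Random(4)
        ref_seq = random_dna(rng, 100)
        ref = SequenceRecord("r", ref_seq)
        contig = SequenceRecord("c", ref_seq[:40] + ref_seq[60:])
        a = make_diagonal(gapless_record("r", "c", ref_seq, 0, 0, 40), "a")
        b = make_diagonal(gapless_record("r", "c", ref_seq, 60, 40, 40), "b")
        aln = traversal_to_alignment(chain([a, b], 100, 80), [a, b], ref, contig)
        assert aln.aligned_ref == ref_seq
        assert aln.aligned_contig == ref_seq[:40] + "-" * 20 + ref_seq[60:]

    def test_leading_unaligned_bases_become_insertions(self):
        rng = random.Random(5)
        ref_seq = random_dna(rng, 60)
        lead = "GGGGG"
        contig = SequenceRecord("c", lead + ref_seq[10:40])
        d = make_diagonal(gapless_record("r", "c", ref_seq, 10, 5, 30), "d0")
        aln = traversal_to_alignment(
            chain([d], 60, 35), [d], SequenceRecord("r", ref_seq), contig
        )
        assert aln.aligned_ref.startswith("-" * 5)
        assert aln.aligned_contig.startswith(lead)
        assert ungapped(aln.aligned_contig) == contig.sequence


# ---------------------------------------------------------------------------
# seeding engines
# ---------------------------------------------------------------------------

class TestFindDiagonals:
    def test_identical_sequences_full_length_diagonal(self):
        rng = random.Random(6)
        seq = random_dna(rng, 100)
        recs = [
            r
            for r in find_diagonals(
                SequenceRecord("c", seq), SequenceRecord("r", seq), k=15
            )
            if r.strand == "+"
        ]
        assert len(recs) == 1
        r = recs[0]
        assert (r.ref_start, r.ref_end, r.contig_start, r.contig_end) == (1, 100, 1, 100)

    def test_no_shared_kmers_gives_empty(self):
        recs = find_diagonals(
            SequenceRecord("c", "G" * 30), SequenceRecord("r", "A" * 100), k=15
        )
        assert recs == []

    def test_reverse_complement_slice_found_on_minus_strand(self):
        rng = random.Random(7)
        ref_seq = random_dna(rng, 200)
        contig_seq = revcomp(ref_seq[50:120])
        recs = find_diagonals(
            SequenceRecord("c", contig_seq), SequenceRecord("r", ref_seq), k=15
        )
        minus = [r for r in recs if r.strand == "-"]
        assert minus
        oracle = brute_force_mems(ref_seq, revcomp(contig_seq), 15)
        assert {(r.ref_start - 1, r.contig_start - 1, r.ref_end - r.ref_start + 1) for r in minus} == set(oracle)

    @pytest.mark.parametrize("seed", range(10))
    def test_internal_seeder_matches_brute_force_mems(self, seed):
        rng = random.Random(4000 + seed)
        ref_seq = random_dna(rng, 80)
        contig_seq = random_dna(rng, 60)
        got = {
            (r.ref_start - 1, r.contig_start - 1, r.ref_end - r.ref_start + 1)
            for r in find_diagonals(
                SequenceRecord("c", contig_seq), SequenceRecord("r", ref_seq), k=5
            )
            if r.strand == "+"
        }
        assert got == set(brute_force_mems(ref_seq, contig_seq, 5))
        assert set(maximal_exact_matches(ref_seq, contig_seq, 5)) == set(
            brute_force_mems(ref_seq, contig_seq, 5)
        )


class TestGlobalAlignContig:
    def test_best_reference_contig_selected(self):
        refs = generate_reference(2, 300, seed=8)
        contig = SequenceRecord("c", refs[1].sequence[100:220])
        aln = global_align_contig(contig, refs, k=15)
        assert aln.ref_id == "chr2" and aln.strand == "+"
        assert ungapped(aln.aligned_contig) == contig.sequence

    def test_unalignable_contig_returns_none(self):
        refs = generate_reference(1, 300, seed=9)
        assert global_align_contig(SequenceRecord("c", "ACGT" * 10), refs, k=15) is None

    def test_minus_strand_preferred_when_better(self):
        refs = generate_reference(1, 400, seed=10)
        contig = SequenceRecord("c", revcomp(refs[0].sequence[50:250]))
        aln = global_align_contig(contig, refs, k=15)
        assert aln.strand == "-"
        assert ungapped(aln.aligned_contig) == revcomp(contig.sequence)

    @pytest.mark.parametrize("seed", range(10))
    def test_character_conservation_and_nw_bound(self, seed):
        """The alignment consumes the whole contig exactly once, and its
        score cannot exceed the exact semi-global NW optimum."""
        rng = random.Random(5000 + seed)
        ref_seq = random_dna(rng, 300)
        s = rng.randint(0, 150)
        contig_seq = ref_seq[s : s + 120]
        contig_seq = contig_seq[:50] + random_dna(rng, 3) + contig_seq[53:]
        aln = global_align_contig(
            SequenceRecord("c", contig_seq), [SequenceRecord("chr1", ref_seq)], k=8
        )
        assert aln is not None
        assert ungapped(aln.aligned_contig) == contig_seq
        assert aln.score <= nw_semiglobal_oracle(ref_seq, contig_seq)
        assert aln.score <= nw_semiglobal_plain(ref_seq, contig_seq)


# ---------------------------------------------------------------------------
# external engines and TSV ingest
# ---------------------------------------------------------------------------

class TestExternalInterfaces:
    def test_unknown_engine_raises_configuration_error(self):
        from novograph.chaining import ConfigurationError

        refs = generate_reference(1, 200, seed=60)
        with pytest.raises(ConfigurationError):
            global_align_contig(SequenceRecord("c", refs[0].sequence[:100]), refs,
                                engine="frobnicate-aligner")

    @pytest.mark.parametrize("engine", ["bwa", "minimap2"])
    def test_external_engine_end_to_end(self, engine):
        import shutil

        if shutil.which(engine) is None:
            pytest.skip(f"{engine} not on PATH")
        refs = generate_reference(1, 3000, seed=61)
        contig = SequenceRecord("c", refs[0].sequence[500:2500])
        aln = global_align_contig(contig, refs, engine=engine)
        assert aln is not None and aln.strand == "+"
        assert ungapped(aln.aligned_contig) == contig.sequence

    def test_tsv_round_trip_feeds_the_chainer(self, tmp_path):
        from novograph.io import read_local_alignments_tsv

        rng = random.Random(62)
        ref_seq = random_dna(rng, 120)
        rec = gapless_record("chr1", "c", ref_seq, 10, 0, 60)
        path = tmp_path / "aln.tsv"
        path.write_text(
            "# contig ref strand rs re cs ce aref acon score\n"
            + "\t".join(
                str(x)
                for x in [
                    rec.contig_id, rec.ref_id, rec.strand, rec.ref_start, rec.ref_end,
                    rec.contig_start, rec.contig_end, rec.aligned_ref,
                    rec.aligned_contig, rec.score,
                ]
            )
            + "\n"
        )
        loaded = read_local_alignments_tsv(path)
        assert loaded == [rec]
        d = make_diagonal(loaded[0], "d0")
        trav = chain([d], 120, 60)
        assert trav.score == 60
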