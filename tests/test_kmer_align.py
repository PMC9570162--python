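import numpy as np
import pytest

from conftest import random_dna
from contigplot.errors import ParameterError
from contigplot.kmer_align import (Anchor, Strand, align_query,
                                   build_kmer_index, merge_anchors,
                                   scan_anchors)
from contigplot.seqio import SequenceRecord, reverse_complement
from oracles import brute_force_mems, segment_key


class TestBuildIndex:
    def test_hand_enumeration_with_repeat(self):
        idx = build_kmer_index(SequenceRecord(id="r", seq="ACGTACGT"), k=4)
        assert idx.table == {"ACGT": [0, 4], "CGTA": [1], "GTAC": [2],
                             "TACG": [3]}

    def test_kmers_overlapping_n_are_skipped(self):
        idx = build_kmer_index(SequenceRecord(id="r", seq="ACNGT"), k=2)
        assert idx.table == {"AC": [0], "GT": [3]}

    def test_position_count_and_ordering(self, rng):
        ref = SequenceRecord(id="r", seq=random_dna(rng, 60))
        k = 8
        idx = build_kmer_index(ref, k)
        n_positions = sum(len(v) for v in idx.table.values())
        assert n_positions == ref.length - k + 1
        assert all(len(key) == k for key in idx.table)
        assert all(v == sorted(v) for v in idx.table.values())

    @pytest.mark.parametrize("k", [0, 9])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ParameterError):
            build_kmer_index(SequenceRecord(id="r", seq="ACGTACGT"), k)


class TestScanAnchors:
    def test_repeat_reference_yields_all_pairs(self):
        idx = build_kmer_index(SequenceRecord(id="r", seq="ACGTACGT"), k=4)
        anchors = scan_anchors(idx, "ACGT", Strand.FORWARD)
        assert anchors == [Anchor(0, 0, Strand.FORWARD),
                           Anchor(0, 4, Strand.FORWARD)]

    def test_all_n_query_yields_nothing(self):
        idx = build_kmer_index(SequenceRecord(id="r", seq="ACGTACGT"), k=4)
        assert scan_anchors(idx, "NNNNNN", Strand.FORWARD) == []

    def test_query_shorter_than_k_is_empty_not_error(self):
        idx = build_kmer_index(SequenceRecord(id="r", seq="ACGTACGT"), k=4)
        assert scan_anchors(idx, "ACG", Strand.FORWARD) == []

    def test_self_scan_sits_on_main_diagonal(self, rng):
        seq = random_dna(rng, 50)
        ref = SequenceRecord(id="r", seq=seq)
        k = 12
        idx = build_kmer_index(ref, k)
        anchors = scan_anchors(idx, seq, Strand.FORWARD)
        diag0 = [a for a in anchors if a.ref_pos == a.query_pos]
        assert len(diag0) == len(seq) - k + 1


class TestMergeAnchors:
    def test_consecutive_run_merges_to_one_segment(self):
        anchors = [Anchor(q, q, Strand.FORWARD) for q in range(7)]
        (seg,) = merge_anchors(anchors, k=4, query_length=10,
                               strand=Strand.FORWARD, query_id="q")
        assert (seg.ref_start, seg.ref_end) == (0, 10)
        assert (seg.query_start, seg.query_end) == (0, 10)
        assert seg.length == 10

    def test_gap_on_diagonal_splits_runs(self):
        anchors = [Anchor(q, q, Strand.FORWARD) for q in (0, 1, 2, 5, 6)]
        segs = merge_anchors(anchors, k=4, query_length=12,
                             strand=Strand.FORWARD, query_id="q")
        assert [(s.ref_start, s.ref_end) for s in segs] == [(0, 6), (5, 10)]

    def test_reverse_strand_coordinates_map_to_forward(self):
        # scanned interval [2, 6) on a 10 bp query -> forward [4, 8)
        anchors = [Anchor(2, 20, Strand.REVERSE)]
        (seg,) = merge_anchors(anchors, k=4, query_length=10,
                               strand=Strand.REVERSE, query_id="q")
        assert (seg.ref_start, seg.ref_end) == (20, 24)
        assert (seg.query_start, seg.query_end) == (4, 8)
        assert seg.strand is Strand.REVERSE


class TestAlignQuery:
    def test_self_alignment_single_forward_cover(self, rng):
        seq = random_dna(rng, 300)
        ref = SequenceRecord(id="r", seq=seq)
        idx = build_kmer_index(ref, 15)
        segs = align_query(idx, SequenceRecord(id="q", seq=seq), 15)
        full = [s for s in segs if s.length == 300]
        assert len(full) == 1 and full[0].strand is Strand.FORWARD
        assert (full[0].ref_start, full[0].query_start) == (0, 0)

    def test_reverse_complement_query_single_reverse_cover(self, rng):
        seq = random_dna(rng, 300)
        ref = SequenceRecord(id="r", seq=seq)
        idx = build_kmer_index(ref, 15)
        segs = align_query(
            idx, SequenceRecord(id="q", seq=reverse_complement(seq)), 15)
        full = [s for s in segs if s.length == 300]
        assert len(full) == 1 and full[0].strand is Strand.REVERSE

    def test_threshold_above_length_empties_output(self, rng):
        seq = random_dna(rng, 100)
        ref = SequenceRecord(id="r", seq=seq)
        idx = build_kmer_index(ref, 10)
        assert align_query(idx, SequenceRecord(id="q", seq=seq), 101) == []

    def test_threshold_below_k_rejected(self, small_reference):
        idx = build_kmer_index(small_reference, 4)
        with pytest.raises(ParameterError):
            align_query(idx, small_reference, 3)

    def test_segment_content_invariant(self, rng):
        ref_seq = random_dna(rng, 400, alphabet="ACG")  # repeats likely
        q_seq = random_dna(rng, 200, alphabet="ACG")
        ref = SequenceRecord(id="r", seq=ref_seq)
        idx = build_kmer_index(ref, 5)
        for seg in align_query(idx, SequenceRecord(id="q", seq=q_seq), 5):
            q_slice = q_seq[seg.query_start:seg.query_end]
            if seg.strand is Strand.REVERSE:
                q_slice = reverse_complement(q_slice)
            assert ref_seq[seg.ref_start:seg.ref_end] == q_slice


class TestOracleEquivalence:
    """Merged segments must equal the brute-force maximal exact match set."""

    @pytest.mark.parametrize("case", range(30))
    def test_matches_brute_force(self, case):
        rng = np.random.default_rng(1000 + case)
        alphabet = "ACGT" if case % 3 else "ACG"  # small alphabet -> repeats
        n = int(rng.integers(40, 500))
        m = int(rng.integers(40, 500))
        k = int(rng.integers(4, 9))
        ref_seq = random_dna(rng, n, alphabet)
        q_seq = random_dna(rng, m, alphabet)
        if case % 5 == 0:  # embed shared material so matches are guaranteed
            pos = int(rng.integers(0, n - 30))
            q_seq = q_seq[:10] + ref_seq[pos:pos + 30] + q_seq[10:]
        ref = SequenceRecord(id="r", seq=ref_seq)
        segs = align_query(build_kmer_index(ref, k),
                           SequenceRecord(id="q", seq=q_seq), k)
        assert {segment_key(s) for s in segs} == \
            brute_force_mems(ref_seq, q_seq, "q", k)


class TestProperties:
    def test_strand_symmetry(self, rng):
        ref_seq = random_dna(rng, 300, alphabet="ACG")
        q_seq = random_dna(rng, 150, alphabet="ACG")
        L = len(q_seq)
        idx = build_kmer_index(SequenceRecord(id="r", seq=ref_seq), 6)
        fwd = align_query(idx, SequenceRecord(id="q", seq=q_seq), 6)
        rev = align_query(
            idx, SequenceRecord(id="q", seq=reverse_complement(q_seq)), 6)
        flipped = {
            (s.ref_start, s.ref_end, L - s.query_end, L - s.query_start,
             Strand.REVERSE if s.strand is Strand.FORWARD else Strand.FORWARD)
            for s in fwd
        }
        assert {segment_key(s) for s in rev} == flipped

    def test_threshold_monotonicity(self, rng):
        ref_seq = random_dna(rng, 400, alphabet="ACG")
        q_seq = random_dna(rng, 200, alphabet="ACG")
        idx = build_kmer_index(SequenceRecord(id="r", seq=ref_seq), 5)
        q = SequenceRecord(id="q", seq=q_seq)
        prev = None
        for threshold in (5, 8, 12, 20):
            segs = {segment_key(s) for s in align_query(idx, q, threshold)}
            if prev is not None:
                assert segs <= prev
            prev = segs

    def test_coverage_non_increasing_in_k(self, rng):
        ref_seq = random_dna(rng, 2000)
        # degrade the query with sparse substitutions to break long matches
        q = list(ref_seq)
        for pos in rng.choice(len(q), size=25, replace=False):
            q[pos] = "ACGT"[(("ACGT".index(q[pos])) + 1) % 4]
        q_seq = "".join(q)
        ref = SequenceRecord(id="r", seq=ref_seq)
        coverages = []
        for k in (8, 12, 16, 24):
            segs = align_query(build_kmer_index(ref, k),
                               SequenceRecord(id="q", seq=q_seq), k)
            covered = set()
            for s in segs:
                covered.update(range(s.ref_start, s.ref_end))
            coverages.append(len(covered))
        assert coverages == sorted(coverages, reverse=True)
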