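"""Aligner: indexing, chaining, breakpoint refinement, circular behavior."""

import itertools

import edlib
import numpy as np
import pytest

from mitolong.align import (
    AlignParams,
    Anchor,
    align_read,
    align_reads,
    chain_anchors,
    collect_anchors,
    index_reference,
    read_alignments_tsv,
    write_alignments_tsv,
    write_sam,
)
from mitolong.refgenome import CircularReference, circular_gap, random_reference, rotate_origin
from mitolong.simulate import reverse_complement


@pytest.fixture(scope="module")
def index(small_ref):
    return index_reference(small_ref, k=15)


class TestIndex:
    def test_doubled_lookup(self):
        ref = CircularReference("t", "ACGTACGT")
        idx = index_reference(ref, k=8, max_occ=50)
        # the 8-mer equals the whole circle; hits at both doubled copies
        hits = idx.lookup("ACGTACGT")
        assert set(h % 8 or 8 for h in hits) <= {1, 5, 8, 4}
        assert any(h <= 8 for h in hits) and any(h > 8 for h in hits)

    def test_absent_kmer_empty(self, index):
        assert index.lookup("N" * 15) == []

    def test_k_range_validated(self, small_ref):
        with pytest.raises(ValueError):
            index_reference(small_ref, k=5)
        with pytest.raises(ValueError):
            index_reference(small_ref, k=40)

    def test_positions_map_back_to_circle(self, index):
        L = index.L
        for positions in list(index.index.values())[:50]:
            assert all(1 <= p <= L for p in positions)


class TestChaining:
    def test_contiguous_anchors_single_chain(self):
        anchors = [Anchor(i, 100 + i, 15) for i in range(1, 50, 5)]
        chain, score = chain_anchors(anchors, max_ref_gap=1000)
        # matched bases telescope, so any co-linear subchain spanning the
        # ends scores identically; the chain must span all anchors gap-free
        assert chain[0] == anchors[0] and chain[-1] == anchors[-1]
        assert score == 15 + (anchors[-1].read_pos - anchors[0].read_pos)
        for a, b in zip(chain, chain[1:]):
            assert b.ref_pos - a.ref_pos == b.read_pos - a.read_pos

    def test_junction_chain_keeps_both_blocks(self, small_ref, index):
        seq = small_ref.sequence
        read = seq[100:300] + seq[700:900]  # ref[101..300] + ref[701..900]
        anchors = collect_anchors(read, index, "+", max_anchors=400)
        chain, _ = chain_anchors(anchors, max_ref_gap=1999)
        ref_jumps = [
            b.ref_pos - a.ref_pos - (b.read_pos - a.read_pos)
            for a, b in zip(chain, chain[1:])
        ]
        big = [g for g in ref_jumps if g > 100]
        assert len(big) == 1
        assert abs(big[0] - 400) < 30

    def test_brute_force_chaining_oracle(self):
        """DP chain score equals exhaustive search over all co-linear subsets."""
        rng = np.random.default_rng(42)
        k, scale = 15, 4.0
        for _ in range(10):
            n = int(rng.integers(4, 10))
            anchors = sorted(
                (Anchor(int(rng.integers(1, 200)), int(rng.integers(1, 2000)), k)
                 for _ in range(n)),
                key=lambda a: (a.read_pos, a.ref_pos),
            )
            chain, score = chain_anchors(anchors, max_ref_gap=5000, gap_open_scale=scale)

            def chain_score(sub):
                s = k
                for a, b in zip(sub, sub[1:]):
                    dr, dg = b.read_pos - a.read_pos, b.ref_pos - a.ref_pos
                    if dr <= 0 or dg <= 0 or dg > 5000 + dr:
                        return None
                    s += min(k, dr) - scale * np.log2(1 + abs(dg - dr))
                return s

            best = max(
                (chain_score(sub)
                 for r in range(1, n + 1)
                 for sub in itertools.combinations(anchors, r)
                 if chain_score(sub) is not None),
            )
            assert score == pytest.approx(best, abs=1e-9)

    def test_equal_score_ties_leftmost(self):
        # two identical chains offset on the reference: leftmost wins
        a1 = [Anchor(1, 100, 15), Anchor(20, 119, 15)]
        a2 = [Anchor(1, 900, 15), Anchor(20, 919, 15)]
        chain, _ = chain_anchors(sorted(a1 + a2, key=lambda a: (a.read_pos, a.ref_pos)),
                                 max_ref_gap=5000)
        assert chain[0].ref_pos == 100

    def test_empty_anchor_list(self):
        chain, score = chain_anchors([], max_ref_gap=100)
        assert chain == [] and score == 0.0


class TestAlignRead:
    def test_exact_substring(self, small_ref, index):
        read = small_ref.sequence[500:1100]
        aln = align_read("r", read, index)
        assert aln.mapped and len(aln.segments) == 1
        seg = aln.segments[0]
        assert (seg.ref_start, seg.ref_end, seg.edit_distance) == (501, 1100, 0)
        assert aln.ref_gaps == []

    def test_error_free_junction_exact_gap(self, small_ref, index):
        seq = small_ref.sequence
        read = seq[100:300] + seq[700:900]
        aln = align_read("r", read, index)
        assert aln.mapped
        assert len(aln.ref_gaps) == 1
        gs, ge = aln.ref_gaps[0]
        assert ge - gs == 400
        assert [s.edit_distance for s in aln.segments] == [0, 0]
        # the reported breakpoint is the leftmost edit-equivalent placement
        # of (301, 701): slide left while the flanking bases coincide
        b, e = 301, 701
        while seq[b - 2] == seq[e - 2]:
            b, e = b - 1, e - 1
        assert (gs, ge) == (b, e)
        assert aln.segments[1].read_start == aln.segments[0].read_end + 1

    def test_origin_spanning_read_single_segment(self, small_ref, index):
        seq = small_ref.sequence
        read = seq[1800:] + seq[:200]  # ref[1801..2000] + ref[1..200]
        aln = align_read("r", read, index)
        assert aln.mapped and len(aln.segments) == 1
        seg = aln.segments[0]
        assert (seg.ref_start, seg.ref_end) == (1801, 200)
        assert aln.ref_gaps == []

    def test_random_read_unmapped(self, index):
        noise = random_reference(5000, seed=999).sequence
        aln = align_read("r", noise, index)
        assert not aln.mapped

    def test_too_short_read_unmapped(self, index):
        assert not align_read("r", "ACGT", index).mapped

    def test_reverse_complement_same_gaps(self, small_ref, index):
        seq = small_ref.sequence
        read = seq[100:300] + seq[700:900]
        fwd = align_read("r", read, index)
        rev = align_read("r", reverse_complement(read), index)
        assert rev.mapped and rev.strand == "-"
        assert rev.ref_gaps == fwd.ref_gaps

    def test_direct_repeat_leftmost_placement(self):
        """A junction flanked by an identical 10-base repeat is placed at the
        leftmost of the edit-distance-equivalent breakpoints."""
        rng_ref = random_reference(2000, seed=31)
        seq = list(rng_ref.sequence)
        repeat = "ACGTTGCAGT"
        seq[300:310] = repeat  # ref[301..310]
        seq[900:910] = repeat  # ref[901..910]
        ref = CircularReference("rep", "".join(seq))
        idx = index_reference(ref, k=15)
        s = ref.sequence
        # molecule deletes ref[311..910]: the read keeps one repeat copy, so
        # every placement sliding the junction through the repeat is
        # edit-equivalent; leftmost is (301, 901)
        read = s[100:310] + s[910:1200]
        aln = align_read("r", read, idx)
        assert aln.mapped and len(aln.ref_gaps) == 1
        gs, ge = aln.ref_gaps[0]
        assert ge - gs == 600
        assert (gs, ge) == (301, 901)

    def test_exhaustive_breakpoint_oracle_with_errors(self):
        """Segment placement matches a brute-force one-gap edit-distance
        oracle on a small reference."""
        ref = random_reference(400, seed=17)
        s = ref.sequence
        rng = np.random.default_rng(3)
        true_b, true_e = 120, 200  # deleted bases 120..199
        mol = s[:119] + s[199:]
        read = mol[40:220]  # spans the junction
        # add a few substitution errors
        read_arr = list(read)
        for pos in rng.choice(len(read), size=4, replace=False):
            read_arr[pos] = "ACGT"[(("ACGT".index(read_arr[pos])) + 1) % 4]
        read = "".join(read_arr)

        idx = index_reference(ref, k=12)
        aln = align_read("r", read, idx, AlignParams(k=12))
        assert aln.mapped and len(aln.ref_gaps) == 1

        # oracle: try all (b, e) deletion placements in a wide window
        best = (10**9, None)
        for b in range(90, 150):
            for e in range(170, 230):
                if e <= b:
                    continue
                template = s[: b - 1] + s[e - 1 :]
                res = edlib.align(read, template, mode="HW", task="distance")
                key = (res["editDistance"], (b, e))
                if key < best:
                    best = key
        oracle_ed, (ob, oe) = best
        gs, ge = aln.ref_gaps[0]
        # equal edit distance; identical placement up to oracle tie-breaking
        template = s[: gs - 1] + s[ge - 1 :]
        ours = edlib.align(read, template, mode="HW", task="distance")["editDistance"]
        assert ours == oracle_ed
        assert ge - gs == oe - ob

    def test_circular_invariance_under_rotation(self, small_ref):
        """Rotating the reference rotates breakpoints but not gap sizes."""
        seq = small_ref.sequence
        reads = [
            ("j1", seq[100:300] + seq[700:900]),
            ("j2", seq[1500:1700] + seq[1900:2000] + seq[:100]),
            ("p1", seq[400:900]),
        ]
        p = 777
        rot = rotate_origin(small_ref, p)
        idx0 = index_reference(small_ref, k=15)
        idx1 = index_reference(rot, k=15)
        L = small_ref.length
        for rid, read in reads:
            a0 = align_read(rid, read, idx0)
            a1 = align_read(rid, read, idx1)
            assert a0.mapped and a1.mapped
            sizes0 = [circular_gap(gs, ge, L) for gs, ge in a0.ref_gaps]
            sizes1 = [circular_gap(gs, ge, L) for gs, ge in a1.ref_gaps]
            assert sizes0 == sizes1
            for (gs0, _), (gs1, _) in zip(a0.ref_gaps, a1.ref_gaps):
                assert ((gs0 - p) % L) + 1 == gs1


class TestExchangeFormats:
    def test_tsv_roundtrip(self, small_ref, index, tmp_path):
        seq = small_ref.sequence
        reads = [("a", seq[100:300] + seq[700:900]), ("b", seq[0:500]),
                 ("noise", random_reference(3000, seed=5).sequence)]
        alns = align_reads(reads, index)
        p = tmp_path / "aln.tsv"
        write_alignments_tsv(alns, p)
        back = read_alignments_tsv(p, small_ref.length)
        assert len(back) == len(alns)
        by_id = {a.read_id: a for a in back}
        for a in alns:
            b = by_id[a.read_id]
            assert b.mapped == a.mapped
            assert b.segments == a.segments
            assert b.ref_gaps == a.ref_gaps

    def test_sam_output_parses(self, small_ref, index, tmp_path):
        import pysam

        seq = small_ref.sequence
        reads = [("a", seq[100:300] + seq[700:900]), ("b", seq[50:650])]
        alns = align_reads(reads, index)
        p = tmp_path / "out.sam"
        write_sam(alns, dict(reads), small_ref, p)
        with pysam.AlignmentFile(str(p)) as fh:
            records = list(fh)
        assert len(records) == 2
        by_name = {r.query_name: r for r in records}
        a = by_name["a"]
        assert a.reference_start == 100
        # CIGAR: query-consuming ops sum to the read length
        qlen = sum(ln for op, ln in a.cigartuples if op in (0, 1, 4, 7, 8))
        assert qlen == 400
        # reference span includes the 400-base N gap
        assert a.reference_end - a.reference_start == 800
        assert a.get_tag("NM") == 0
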