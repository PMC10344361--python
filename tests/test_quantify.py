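"""Coverage profile, heteroplasmy estimators, downsampling, recommendations."""

import numpy as np
import pytest

from mitolong.align import ReadAlignment, Segment
from mitolong.quantify import (
    CoverageProfile,
    Recommendation,
    coverage_profile,
    downsample,
    enzyme_exclusion_zones,
    heteroplasmy_coverage_ratio,
    heteroplasmy_spanning_reads,
    mtdna_ratio,
    recommend_next_step,
    write_bedgraph,
)
from mitolong.refgenome import CircularReference, random_reference
from mitolong.svcall import DeletionCall

L = 2000


def _ref():
    return random_reference(L, seed=1)


def _aln(read_id, segments, gaps=()):
    segs = [Segment(*s) for s in segments]
    return ReadAlignment(read_id, "+", segs, list(gaps), True,
                         sum(s[1] - s[0] + 1 for s in segments))


class TestCoverageProfile:
    def test_two_reads_sum(self):
        alns = [_aln("a", [(1, 100, 1, 100, 0)]), _aln("b", [(1, 100, 1, 100, 0)])]
        prof = coverage_profile(alns, _ref())
        assert prof.depth[:100].tolist() == [2] * 100
        assert prof.depth[100:].sum() == 0
        assert prof.depth.sum() == 200
        assert prof.n_reads == 2

    def test_junction_read_skips_gap(self):
        alns = [_aln("a", [(1, 200, 101, 300, 0), (201, 400, 701, 900, 0)],
                     gaps=[(301, 701)])]
        prof = coverage_profile(alns, _ref())
        assert prof.depth[300:700].sum() == 0
        assert prof.depth[100:300].tolist() == [1] * 200

    def test_wrapping_segment(self):
        alns = [_aln("a", [(1, 200, 1901, 100, 0)])]
        prof = coverage_profile(alns, _ref())
        assert prof.depth[1900:].tolist() == [1] * 100
        assert prof.depth[:100].tolist() == [1] * 100

    def test_empty(self):
        prof = coverage_profile([], _ref())
        assert prof.depth.sum() == 0 and prof.n_reads == 0


class TestCoverageRatio:
    def _profile(self, inside_depth, outside_depth, start=500, end=1000):
        depth = np.full(L, outside_depth, dtype=np.int64)
        depth[start - 1 : end - 1] = inside_depth
        return CoverageProfile(depth=depth, n_reads=1)

    def test_simple_ratio(self):
        prof = self._profile(40, 100)
        call = DeletionCall(500, 1000, 500, 10)
        assert heteroplasmy_coverage_ratio(prof, call, margin=100) == pytest.approx(0.60)

    def test_homoplasmic(self):
        prof = self._profile(0, 100)
        call = DeletionCall(500, 1000, 500, 10)
        assert heteroplasmy_coverage_ratio(prof, call, margin=100) == 1.0

    def test_margin_trims_breakpoint_noise(self):
        prof = self._profile(40, 100)
        # contaminate 50 bases inside each breakpoint; the margin hides it
        prof.depth[499:549] = 100
        call = DeletionCall(500, 1000, 500, 10)
        assert heteroplasmy_coverage_ratio(prof, call, margin=100) == pytest.approx(0.60)

    def test_excluded_regions_removed_from_outside(self):
        prof = self._profile(40, 100)
        prof.depth[1500:1600] = 1000  # linearization spike
        call = DeletionCall(500, 1000, 500, 10)
        h_spiked = heteroplasmy_coverage_ratio(prof, call, margin=100)
        h_clean = heteroplasmy_coverage_ratio(
            prof, call, margin=100, excluded_regions=[(1501, 1600)]
        )
        assert h_clean == pytest.approx(0.60)
        assert h_spiked > h_clean

    def test_empty_interval_error(self):
        prof = self._profile(40, 100)
        call = DeletionCall(500, 640, 140, 10)
        with pytest.raises(ValueError, match="empty"):
            heteroplasmy_coverage_ratio(prof, call, margin=100)

    def test_zero_outside_error(self):
        prof = CoverageProfile(depth=np.zeros(L, dtype=np.int64), n_reads=0)
        call = DeletionCall(500, 1000, 500, 10)
        with pytest.raises(ValueError):
            heteroplasmy_coverage_ratio(prof, call, margin=100)

    def test_enzyme_zones(self):
        zones = enzyme_exclusion_zones([100], 2000, halfwidth=300)
        assert zones == [(1800, 400)]


class TestSpanningReads:
    def _junction(self, rid):
        return _aln(rid, [(1, 200, 301, 500, 0), (201, 400, 1001, 1200, 0)],
                    gaps=[(501, 1001)])

    def _crossing(self, rid, pos):
        return _aln(rid, [(1, 400, pos - 200, pos + 199, 0)])

    def test_balanced(self):
        call = DeletionCall(501, 1001, 500, 10)
        alns = [self._junction(f"j{i}") for i in range(10)]
        alns += [self._crossing(f"s{i}", 501) for i in range(10)]
        alns += [self._crossing(f"e{i}", 1001) for i in range(10)]
        h = heteroplasmy_spanning_reads(alns, call, L)
        assert h == pytest.approx(10 / (10 + 10))

    def test_no_junctions_zero(self):
        call = DeletionCall(501, 1001, 500, 10)
        alns = [self._crossing("s", 501)]
        assert heteroplasmy_spanning_reads(alns, call, L) == 0.0

    def test_undefined_is_none(self):
        call = DeletionCall(501, 1001, 500, 10)
        alns = [_aln("far", [(1, 50, 1700, 1749, 0)])]
        assert heteroplasmy_spanning_reads(alns, call, L) is None

    def test_min_flank_excludes_thin_junctions(self):
        call = DeletionCall(501, 1001, 500, 10)
        thin = _aln("t", [(1, 10, 491, 500, 0), (11, 300, 1001, 1290, 0)],
                    gaps=[(501, 1001)])
        h = heteroplasmy_spanning_reads([thin, self._crossing("w", 1001)], call, L,
                                        min_flank=50)
        assert h == 0.0


class TestDownsample:
    def _alignments(self, n, span=400):
        rng = np.random.default_rng(7)
        out = []
        for i in range(n):
            s = int(rng.integers(1, L))
            e = ((s + span - 1 - 1) % L) + 1
            out.append(_aln(f"r{i}", [(1, span, s, e, 0)]))
        return out

    def test_identity_when_target_equals_current(self, rng):
        alns = self._alignments(50)
        ref = _ref()
        cur = coverage_profile(alns, ref).mean_depth
        assert len(downsample(alns, cur, ref, rng)) == 50

    def test_binomial_retention(self, rng):
        alns = self._alignments(5000)
        ref = _ref()
        cur = coverage_profile(alns, ref).mean_depth  # 1000x
        sub = downsample(alns, cur / 5, ref, rng)
        assert abs(len(sub) / 5000 - 0.2) < 0.02

    def test_target_above_current_rejected(self, rng):
        alns = self._alignments(10)
        with pytest.raises(ValueError):
            downsample(alns, 10_000, _ref(), rng)

    def test_conservation_after_downsampling(self, rng):
        alns = self._alignments(200)
        ref = _ref()
        sub = downsample(alns, 20, ref, rng)
        prof = coverage_profile(sub, ref)
        expected = sum(
            s.read_end - s.read_start + 1 for a in sub for s in a.segments
        )
        assert prof.depth.sum() == expected
        assert prof.mean_depth <= 20

    def test_seed_deterministic(self):
        alns = self._alignments(300)
        ref = _ref()
        a = downsample(alns, 20, ref, np.random.default_rng(5))
        b = downsample(alns, 20, ref, np.random.default_rng(5))
        assert [x.read_id for x in a] == [x.read_id for x in b]


class TestMtdnaRatio:
    def test_typical_rapid_kit_read_counts(self):
        # typical Rapid-kit run: 176,790 reads total, 2,184 on the mt genome
        assert mtdna_ratio(2_184, 176_790 - 2_184) == pytest.approx(0.01251, abs=2e-5)

    def test_equal_counts(self):
        assert mtdna_ratio(5, 5) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            mtdna_ratio(10, 0)


class TestRecommendation:
    def test_negative(self):
        assert recommend_next_step([], [100], "endonuclease", L) is Recommendation.DONE_NEGATIVE
        assert recommend_next_step([], [], "transposase", L) is Recommendation.DONE_NEGATIVE

    def test_single_deletion_site_outside(self):
        call = DeletionCall(8_482, 13_446, 4_964, 5)
        rec = recommend_next_step([call], [14_262], "endonuclease", 16_569)
        assert rec is Recommendation.DONE_SINGLE_DELETION

    def test_single_deletion_site_inside(self):
        call = DeletionCall(7_634, 13_956, 6_322, 5)
        rec = recommend_next_step([call], [13_000], "endonuclease", 16_569)
        assert rec is Recommendation.REDIGEST_PVUII

    def test_multiple_calls_endonuclease(self):
        calls = [DeletionCall(500, 900, 400, 3), DeletionCall(1200, 1500, 300, 3)]
        assert recommend_next_step(calls, [100], "endonuclease", L) is Recommendation.USE_RAPID_KIT

    def test_transposase_always_terminal(self):
        calls = [DeletionCall(500, 900, 400, 3), DeletionCall(1200, 1500, 300, 3)]
        rec = recommend_next_step(calls, [], "transposase", L)
        assert rec is Recommendation.DONE_MULTIPLE_DELETIONS
        rec1 = recommend_next_step(calls[:1], [], "transposase", L)
        assert rec1 is Recommendation.DONE_SINGLE_DELETION


def test_bedgraph_runs(tmp_path):
    depth = np.array([0, 0, 3, 3, 3, 1], dtype=np.int64)
    prof = CoverageProfile(depth=depth, n_reads=2)
    p = tmp_path / "c.bedgraph"
    write_bedgraph(prof, "chrM", p)
    assert p.read_text() == "chrM\t0\t2\t0\nchrM\t2\t5\t3\nchrM\t5\t6\t1\n"
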