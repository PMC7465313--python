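"""Read statistics, enrichment report, depth/bins and off-target calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import capxcise as cx
from capxcise.qc import AlignmentRecord


def rec(qname, tname, tstart, tend, strand="+", mapq=60, tlen=100_000,
        qlen=None):
    span = tend - tstart
    qlen = qlen or span
    return AlignmentRecord(qname=qname, qlen=qlen, qstart=0, qend=min(qlen, span),
                           strand=strand, tname=tname, tlen=tlen,
                           tstart=tstart, tend=tend, nmatch=span,
                           blocklen=span, mapq=mapq)


def brute_force_n50(lengths):
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L


class TestReadStats:
    def test_single_read(self):
        stats = cx.read_stats([(7000, 12.0)])
        assert stats.n50 == 7000 and stats.median_length == 7000

    def test_n50_from_cumulative_sum(self):
        # lengths 1..5 kb: 5+4 = 9 >= 7.5, so N50 = 4,000
        stats = cx.read_stats([(L, 10.0) for L in (1000, 2000, 3000, 4000, 5000)])
        assert stats.n50 == 4000

    @given(st.lists(st.integers(1, 50_000), min_size=1, max_size=100))
    def test_n50_equals_exhaustive_oracle(self, lengths):
        assert cx.n50(lengths) == brute_force_n50(lengths)

    def test_pass_threshold_is_inclusive(self):
        stats = cx.read_stats([(1000, 6.9), (1000, 7.0), (1000, 7.1)])
        assert stats.pass_reads == 2

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            cx.read_stats([])


class TestEnrichmentReport:
    WIN = ("c", 10_001, 20_000)

    def test_all_reads_inside_window(self):
        records = [rec(f"r{i}", "c", 12_000, 15_000) for i in range(5)]
        rep = cx.enrichment_report(records, self.WIN)
        assert rep.on_target_percentage == 100.0

    def test_constructed_30_of_1000(self):
        records = [rec(f"on{i}", "c", 11_000, 14_000) for i in range(30)]
        records += [rec(f"off{i}", "c", 50_000, 60_000) for i in range(970)]
        rep = cx.enrichment_report(records, self.WIN)
        assert rep.on_target_coverage == 30
        assert rep.on_target_percentage == pytest.approx(3.0)

    def test_coverage_is_forward_plus_reverse(self):
        records = ([rec(f"f{i}", "c", 11_000, 12_000, "+") for i in range(3)]
                   + [rec(f"r{i}", "c", 11_000, 12_000, "-") for i in range(2)])
        rep = cx.enrichment_report(records, self.WIN)
        assert (rep.on_target_forward, rep.on_target_reverse) == (3, 2)
        assert rep.on_target_coverage == 5

    def test_one_bp_overlap_counts(self):
        edge = rec("e", "c", 9_000, 10_001)   # covers 1-based position 10001
        out = rec("o", "c", 9_000, 10_000)    # stops just before the window
        rep = cx.enrichment_report([edge, out], self.WIN)
        assert rep.on_target_coverage == 1

    def test_best_alignment_decides_membership(self):
        primary = rec("r", "c", 50_000, 60_000, mapq=60)
        secondary = rec("r", "c", 11_000, 12_000, mapq=10)
        rep = cx.enrichment_report([primary, secondary], self.WIN)
        assert rep.on_target_coverage == 0 and rep.aligned_reads == 1

    def test_empty_input_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            rep = cx.enrichment_report([], self.WIN)
        assert rep.empty_input and rep.aligned_reads == 0


class TestDepth:
    def test_single_alignment_unit_depth(self):
        d = cx.per_base_depth([rec("r", "c", 9, 20, tlen=50)])
        vec = d["c"]
        assert vec[9:20].tolist() == [1] * 11
        assert vec[:9].sum() == 0 and vec[20:].sum() == 0

    def test_overlap_adds(self):
        d = cx.per_base_depth([rec("a", "c", 0, 10, tlen=30),
                               rec("b", "c", 5, 15, tlen=30)])
        assert d["c"][7] == 2 and d["c"][2] == 1 and d["c"][12] == 1

    def test_random_alignments_match_brute_force(self):
        rng = np.random.default_rng(2)
        records = []
        for i in range(50):
            s = int(rng.integers(0, 900))
            e = s + int(rng.integers(1, 100))
            records.append(rec(f"r{i}", "c", s, e, tlen=1000,
                               mapq=int(rng.integers(0, 61))))
        for threshold in (0, 30):
            got = cx.per_base_depth(records, min_mapq=threshold)["c"]
            expect = np.zeros(1000, dtype=int)
            for r in records:
                if r.mapq >= threshold:
                    expect[r.tstart:r.tend] += 1
            assert got.tolist() == expect.tolist()

    def test_total_depth_equals_block_length_sum(self):
        rng = np.random.default_rng(9)
        records = [rec(f"r{i}", f"c{i % 3}", int(s := rng.integers(0, 500)),
                       int(s) + int(rng.integers(1, 400)), tlen=1000)
                   for i in range(30)]
        depth = cx.per_base_depth(records, min_mapq=0)
        total = sum(v.sum() for v in depth.values())
        assert total == sum(r.blocklen for r in records)


class TestBinsAndOfftargets:
    def test_uniform_depth_uniform_bins(self):
        records = [rec(f"r{i}", "c", 0, 10_000, tlen=10_000) for i in range(4)]
        bins = cx.bin_coverage(records, bin_size=1000, min_mapq=0)
        assert all(b.depth == pytest.approx(4.0) for b in bins)

    def test_confined_pileup_hits_one_bin(self):
        records = [rec(f"r{i}", "c", 3_100, 3_900, tlen=10_000)
                   for i in range(30)]
        bins = cx.bin_coverage(records, bin_size=1000, min_mapq=0)
        nonzero = [b for b in bins if b.depth > 0]
        assert len(nonzero) == 1 and nonzero[0].start == 3001

    def test_bins_equal_recomputation_from_depth(self):
        rng = np.random.default_rng(4)
        records = [rec(f"r{i}", "c", int(s := rng.integers(0, 8000)),
                       int(s) + int(rng.integers(1, 2000)), tlen=10_000)
                   for i in range(40)]
        bins = cx.bin_coverage(records, bin_size=700, min_mapq=0)
        depth = cx.per_base_depth(records, min_mapq=0)["c"]
        for b in bins:
            assert b.depth == pytest.approx(depth[b.start - 1:b.end].mean())

    def test_uniform_background_below_threshold_is_empty(self):
        records = [rec(f"r{i}", "c", 0, 50_000, tlen=50_000) for i in range(5)]
        bins = cx.bin_coverage(records, min_mapq=0)
        assert cx.detect_offtargets(bins, ("c", 1, 100)) == []

    def test_planted_pileup_recovered_with_bounds_and_coverage(self):
        # depth-40 pileup spanning three 1 kb bins, away from the window
        records = [rec(f"bg{i}", "c", 0, 50_000, tlen=50_000) for i in range(5)]
        records += [rec(f"p{i}", "c", 30_000, 33_000, tlen=50_000)
                    for i in range(40)]
        regions = cx.find_offtarget_regions(records, ("c", 1, 1000),
                                            min_mapq=0)
        assert len(regions) == 1
        r = regions[0]
        assert abs(r.start - 30_001) <= 1000 and abs(r.end - 33_000) <= 1000
        assert r.max_coverage == pytest.approx(45.0)

    def test_low_mapq_pileup_is_gated_out(self):
        records = [rec(f"p{i}", "c", 30_000, 33_000, tlen=50_000, mapq=20)
                   for i in range(30)]
        regions = cx.find_offtarget_regions(records, ("c", 1, 1000),
                                            min_mapq=40)
        assert regions == []

    def test_window_overlap_excluded(self):
        records = [rec(f"p{i}", "c", 30_000, 33_000, tlen=50_000)
                   for i in range(40)]
        assert cx.find_offtarget_regions(records, ("c", 30_500, 31_000),
                                         min_mapq=0) == []

    def test_raising_threshold_never_adds_regions(self):
        rng = np.random.default_rng(13)
        records = []
        for i in range(200):
            s = int(rng.integers(0, 40_000))
            records.append(rec(f"r{i}", "c", s, s + int(rng.integers(500, 5000)),
                               tlen=50_000))
        bins = cx.bin_coverage(records, min_mapq=0)
        prev = None
        for thr in (5, 10, 20, 40):
            regions = cx.detect_offtargets(bins, ("c", 1, 10), min_coverage=thr)
            spans = {(r.contig, r.start, r.end) for r in regions}
            if prev is not None:
                covered = {
                    (c, s, e) for c, s, e in spans
                    if any(pc == c and ps <= s and pe >= e for pc, ps, pe in prev)}
                assert covered == spans   # every region nests in a previous one
            prev = spans


class TestAlignmentIO:
    def test_paf_round_trip(self, tmp_path):
        records = [rec(f"r{i}", "c", i * 10, i * 10 + 100) for i in range(5)]
        cx.write_paf(records, tmp_path / "a.paf")
        assert cx.read_paf(tmp_path / "a.paf") == records

    def test_sam_reader_maps_to_paf_convention(self, tmp_path):
        sam = (tmp_path / "toy.sam")
        sam.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "@SQ\tSN:c\tLN:1000\n"
            "r1\t0\tc\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r2\t16\tc\t201\t40\t30M\t*\t0\t0\t" + "C" * 30 + "\t*\n")
        got = cx.read_sam(sam)
        assert [(r.qname, r.tstart, r.tend, r.strand, r.mapq) for r in got] == [
            ("r1", 100, 150, "+", 60), ("r2", 200, 230, "-", 40)]
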