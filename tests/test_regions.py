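import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apafind.core import CoverageTrack, PolyASiteSet, TerminalRegion, TranscriptModel
from apafind.regions import (
    bin_region,
    extend_region,
    extension_length,
    extract_terminal_exon,
    merge_regions,
    refine_region,
)


def tx(exons, strand="+", tid="t", chrom="chr1"):
    return TranscriptModel(tid, "g", chrom, strand, tuple(exons))


def flat_cov(depth, n=2_000_000, chrom="chr1"):
    return CoverageTrack({(chrom, "."): np.full(n, float(depth))}, stranded=False)


class TestExtractTerminal:
    def test_plus_strand_last_exon(self):
        r = extract_terminal_exon(tx([(1, 100), (201, 300)]))
        assert (r.start, r.end) == (201, 300)
        assert r.original_stops == (300,)

    def test_minus_strand_first_exon(self):
        r = extract_terminal_exon(tx([(1, 100), (201, 300)], strand="-"))
        assert (r.start, r.end) == (1, 100)
        assert r.original_stops == (1,)

    def test_single_exon_whole_transcript(self):
        r = extract_terminal_exon(tx([(50, 400)]))
        assert (r.start, r.end) == (50, 400)


class TestExtend:
    def test_default_extension_is_10200(self):
        r = extract_terminal_exon(tx([(801, 1000)]))
        out = extend_region(r, 100, [], chrom_length=10**6)
        assert out.end == 1000 + 10_200
        assert extension_length(100) == 10_200

    def test_bin_50_extension_is_10100(self):
        assert extension_length(50) == 10_100
        r = extract_terminal_exon(tx([(801, 1000)]))
        assert extend_region(r, 50, [], 10**6).end == 11_100

    def test_neighbor_clips_extension(self):
        r = extract_terminal_exon(tx([(801, 1000)]))
        neighbor = tx([(5000, 5400)], tid="n")
        assert extend_region(r, 100, [neighbor], 10**6).end == 4_999

    def test_never_shortened_past_original_stop(self):
        r = extract_terminal_exon(tx([(801, 1000)]))
        overlapping = tx([(900, 1500)], tid="n")
        assert extend_region(r, 100, [overlapping], 10**6).end == 1000

    def test_clipped_at_chromosome_end(self):
        r = extract_terminal_exon(tx([(801, 1000)]))
        assert extend_region(r, 100, [], chrom_length=2000).end == 2000

    def test_minus_strand_mirror(self):
        r = extract_terminal_exon(tx([(20_000, 20_500), (21_000, 21_200)], strand="-"))
        out = extend_region(r, 100, [], 10**6)
        assert out.start == 20_000 - 10_200
        neighbor = tx([(12_000, 15_000)], strand="-", tid="n")
        assert extend_region(r, 100, [neighbor], 10**6).start == 15_001


class TestRefine:
    def test_uniform_depth_unchanged(self):
        r = extract_terminal_exon(tx([(801, 1000)]))
        ext = extend_region(r, 100, [], 10**6)
        assert refine_region(ext, flat_cov(100), 100) == ext

    def test_zero_beyond_stop_removes_extension(self):
        arr = np.zeros(20_000)
        arr[:1000] = 100.0
        cov = CoverageTrack({("chr1", "."): arr}, stranded=False)
        r = extend_region(extract_terminal_exon(tx([(801, 1000)])), 100, [], 20_000)
        assert refine_region(r, cov, 100).end == 1000

    def test_step_profile_truncates_before_low_window(self):
        # successive 100-base windows after the stop: 100, 50, 2, 0
        arr = np.zeros(20_000)
        arr[:1000] = 100.0
        arr[1000:1100] = 100.0
        arr[1100:1200] = 50.0
        arr[1200:1300] = 2.0
        cov = CoverageTrack({("chr1", "."): arr}, stranded=False)
        r = extend_region(extract_terminal_exon(tx([(801, 1000)])), 100, [], 20_000)
        assert refine_region(r, cov, 100).end == 1200

    def test_idempotent(self):
        arr = np.zeros(20_000)
        arr[:1250] = 100.0
        cov = CoverageTrack({("chr1", "."): arr}, stranded=False)
        r = extend_region(extract_terminal_exon(tx([(801, 1000)])), 100, [], 20_000)
        once = refine_region(r, cov, 100)
        assert refine_region(once, cov, 100) == once

    def test_never_shorter_than_terminal_exon(self):
        cov = flat_cov(0, 20_000)
        r = extend_region(extract_terminal_exon(tx([(801, 1000)])), 100, [], 20_000)
        out = refine_region(r, cov, 100)
        assert (out.start, out.end) == (801, 1000)

    def test_minus_strand_mirror(self):
        arr = np.zeros(40_000)
        arr[19_899:21_000] = 100.0  # depth over 19_900..21_000
        cov = CoverageTrack({("chr1", "."): arr}, stranded=False)
        r = extend_region(
            extract_terminal_exon(tx([(20_000, 20_500)], strand="-")),
            100, [], 40_000,
        )
        out = refine_region(r, cov, 100)
        assert out.start == 19_900  # one clean window survives below the stop
        assert out.end == 20_500


def region(start, end, strand="+", stops=None, chrom="chr1"):
    stops = stops or (end if strand == "+" else start,)
    if isinstance(stops, int):
        stops = (stops,)
    return TerminalRegion(chrom, strand, start, end, ("t",), tuple(stops))


class TestMerge:
    def test_overlap_union(self):
        merged = merge_regions([region(100, 500), region(400, 900)])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 900)
        assert len(merged[0].original_stops) == 2
        assert merged[0].merged

    def test_opposite_strands_not_merged(self):
        merged = merge_regions([region(100, 500), region(400, 900, strand="-")])
        assert len(merged) == 2

    def test_adjacent_not_merged(self):
        assert len(merge_regions([region(100, 500), region(501, 900)])) == 2

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.tuples(st.integers(1, 5000), st.integers(1, 400)),
            min_size=1, max_size=50,
        )
    )
    def test_matches_sweep_line_oracle(self, intervals):
        regs = [region(s, s + ln) for s, ln in intervals]
        merged = sorted(
            (r.start, r.end) for r in merge_regions(regs)
        )
        # brute force: mark covered bases, read off runs
        hit = np.zeros(6000, dtype=bool)
        for s, ln in intervals:
            hit[s : s + ln + 1] = True
        runs, start = [], None
        for i in range(6000):
            if hit[i] and start is None:
                start = i
            elif not hit[i] and start is not None:
                runs.append((start, i - 1))
                start = None
        assert merged == runs


class TestBinRegion:
    def test_300_bins_remnant_dropped_one_chunk(self):
        r = region(1, 30_050)
        (bs,) = bin_region(r, 100, 300)
        assert bs.n_real == 300
        assert bs.ends[299] == 30_000  # 50-base remnant dropped
        assert bs.mask.all()

    def test_short_region_padded(self):
        (bs,) = bin_region(region(1, 250), 100, 300)
        assert bs.n_real == 2
        assert (~bs.mask[2:]).all()
        assert bs.starts[2:].sum() == 0

    def test_sub_bin_region_skipped(self):
        assert bin_region(region(1, 60), 100, 300) == []

    def test_minus_strand_tiles_from_3prime_high_end(self):
        (bs,) = bin_region(region(1, 250, strand="-"), 100, 300)
        assert (bs.starts[0], bs.ends[0]) == (151, 250)
        assert (bs.starts[1], bs.ends[1]) == (51, 150)

    def test_long_region_chunks(self):
        chunks = bin_region(region(1, 70_000), 100, 300)
        assert [c.n_real for c in chunks] == [300, 300, 100]
        assert chunks[0].ends[299] + 1 == chunks[1].starts[0]

    @pytest.mark.parametrize("pos", [1, 99, 100, 101, 199, 200])
    def test_site_labels_exactly_one_containing_bin(self, pos):
        sites = PolyASiteSet([("chr1", "+", pos)])
        (bs,) = bin_region(region(1, 299), 100, 300, labels=sites)
        labeled = [
            i for i in range(bs.n_real) if bs.labels[i]
        ]
        expected = [
            i for i in range(bs.n_real)
            if bs.starts[i] <= pos <= bs.ends[i]
        ]
        assert labeled == expected and len(labeled) == 1

    @pytest.mark.parametrize("pos", [250, 299])
    def test_site_in_dropped_remnant_is_unlabeled(self, pos):
        # the trailing 99-base remnant carries no bin, hence no label
        sites = PolyASiteSet([("chr1", "+", pos)])
        (bs,) = bin_region(region(1, 299), 100, 300, labels=sites)
        assert not bs.labels.any()

    def test_label_count_conserved(self, small_fixture, small_sequences):
        planted_in_bins = 0
        for bs in small_sequences:
            for i in range(bs.n_real):
                planted_in_bins += len(
                    small_fixture.sites.in_interval(
                        bs.chrom, bs.strand, int(bs.starts[i]), int(bs.ends[i])
                    )
                )
        total_labels = sum(int(bs.labels[bs.mask].sum()) for bs in small_sequences)
        assert total_labels <= planted_in_bins  # a bin can hold >1 site
        # every bin holding >=1 site is labeled 1 and no other bin is
        for bs in small_sequences:
            for i in range(bs.n_real):
                n_here = len(
                    small_fixture.sites.in_interval(
                        bs.chrom, bs.strand, int(bs.starts[i]), int(bs.ends[i])
                    )
                )
                assert bool(bs.labels[i]) == (n_here > 0)

    def test_bins_disjoint_within_region(self, small_sequences):
        for bs in small_sequences:
            widths = bs.ends[bs.mask] - bs.starts[bs.mask] + 1
            assert (widths == bs.bin_size).all()
            assert bs.starts[bs.mask].min() >= bs.region.start
            assert bs.ends[bs.mask].max() <= bs.region.end
            ivs = sorted(zip(bs.starts[bs.mask], bs.ends[bs.mask]))
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 > e1
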