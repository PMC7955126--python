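import numpy as np
import pytest

from apafind import pipeline
from apafind.core import (
    CoverageTrack,
    GenomeSequence,
    PolyASiteSet,
    TerminalRegion,
    TranscriptModel,
    reverse_complement,
)
from apafind.features import (
    FeatureConfig,
    N_FEATURES,
    RNA_SLICE,
    annot_end_feature,
    build_window,
    featurize,
    rna_features,
    scan_elements,
    scan_pas,
)
from apafind.regions import bin_region
from apafind.synthetic import SimConfig, generate

CFG = FeatureConfig()


def window_with(motif, offset, background="C", n=300):
    s = background * n
    return s[:offset] + motif + s[offset + len(motif) :]


class TestWindow:
    @pytest.fixture()
    def genome(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        return GenomeSequence({"chr1": seq})

    @pytest.fixture()
    def cov(self):
        return CoverageTrack(
            {("chr1", "."): np.arange(2000, dtype=float)}, stranded=False
        )

    def test_plus_strand_window_is_literal_genomic(self, genome, cov):
        seq, depth = build_window(501, 600, "+", "chr1", genome, cov)
        assert seq == genome.fetch("chr1", 401, 700)
        assert np.array_equal(depth, np.arange(400, 700))

    def test_minus_strand_window_is_revcomp_and_reversed(self, genome, cov):
        seq, depth = build_window(501, 600, "-", "chr1", genome, cov)
        assert seq == reverse_complement(genome.fetch("chr1", 401, 700))
        assert np.array_equal(depth, np.arange(400, 700)[::-1])

    def test_chromosome_start_fill(self, genome, cov):
        seq, depth = build_window(1, 100, "+", "chr1", genome, cov)
        assert seq[:100] == "N" * 100
        assert depth[:100].sum() == 0


class TestScanPas:
    def test_canonical_detected_with_position(self):
        feats, pos = scan_pas(window_with("AATAAA", 120))
        assert list(feats) == [1, -1, -1, -1]
        assert pos == 120

    def test_no_match_all_negative(self):
        feats, pos = scan_pas("C" * 300)
        assert list(feats) == [-1, -1, -1, -1]
        assert pos is None

    def test_priority_canonical_over_variant(self):
        w = window_with("ATTAAA", 80)
        w = w[:150] + "AATAAA" + w[156:]
        feats, pos = scan_pas(w)
        assert feats[0] == 1 and feats[1] == 1
        assert pos == 150

    def test_match_outside_scan_region_ignored(self):
        feats, pos = scan_pas(window_with("AATAAA", 40))
        assert feats[0] == -1 and pos is None
        feats, _ = scan_pas(window_with("AATAAA", 230))
        assert feats[0] == -1

    def test_matches_brute_force_oracle(self, rng):
        from apafind.features import (
            PAS_CANONICAL, PAS_MINOR, PAS_VARIANT_1, PAS_VARIANT_2,
        )

        groups = [(PAS_CANONICAL,), (PAS_VARIANT_1,), (PAS_VARIANT_2,), PAS_MINOR]
        for _ in range(50):
            w = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
            feats, pos = scan_pas(w)
            expected_pos = None
            for gi, motifs in enumerate(groups):
                hits = [
                    o for o in range(CFG.pas_scan_start, CFG.pas_scan_end - 5)
                    for m in motifs if w[o : o + 6] == m
                ]
                assert (feats[gi] == 1) == bool(hits)
                if hits and expected_pos is None:
                    expected_pos = max(hits)
            assert pos == expected_pos


class TestScanElements:
    def test_poly_c_all_negative(self):
        assert list(scan_elements("C" * 300, None)) == [-1] * 8

    def test_g_rich_downstream(self):
        w = window_with("GGGAAGGGAAGGG", 130, background="C")
        feats = scan_elements(w, 120)
        assert feats[0] == 1

    def test_t_rich_downstream_of_pas(self):
        w = window_with("T" * 30, 126, background="C")
        feats = scan_elements(w, 120)
        assert feats[4] == 1  # T-rich immediately downstream

    def test_enrichment_direction_on_synthetic_windows(self, small_fixture,
                                                       small_sequences):
        X = np.concatenate([bs.X[bs.mask] for bs in small_sequences])
        y = np.concatenate([bs.labels[bs.mask] for bs in small_sequences])
        # GTGT/TGTG downstream: planted GU-rich element vs chance occurrence
        col = 3
        assert (X[y == 1, col] == 1).mean() > (X[y == 0, col] == 1).mean()


class TestRnaFeatures:
    def test_flat_coverage_all_contrasts_zero(self):
        w = np.full(300, 7.0)
        out = rna_features(w, (7.0, 7.0, 7.0))
        s_feats = out[[0, 1, 2, 4, 5, 7, 8, 9, 11, 12]]
        assert np.allclose(s_feats, 0)
        assert out[3] == pytest.approx(np.log1p(7.0))

    def test_step_at_bin_3prime_edge(self):
        w = np.concatenate([np.full(200, 100.0), np.zeros(100)])
        out = rna_features(w, (100.0, 100.0, 0.0))
        assert out[1] == pytest.approx(100 / 101)  # s(mM, mD) intra
        assert out[8] == pytest.approx(100 / 101)  # s(MM, MD) inter

    def test_bounded(self, rng):
        for _ in range(20):
            w = rng.integers(0, 1000, 300).astype(float)
            inter = tuple(rng.integers(0, 1000, 3).astype(float))
            out = rna_features(w, inter)
            assert np.isfinite(out).all()
            assert (np.abs(out[[0, 1, 2]]) < 1).all()

    def test_matches_straight_line_recomputation(self, rng):
        for _ in range(20):
            w = rng.integers(0, 500, 300).astype(float)
            mu, mm, md = (np.median(w[:100]), np.median(w[100:200]),
                          np.median(w[200:]))
            MU, MM, MD = rng.integers(0, 500, 3).astype(float)
            out = rna_features(w, (MU, MM, MD))
            exp = []
            for (u, m, d) in ((mu, mm, md), (MU, MM, MD)):
                exp += [
                    (u - m) / (u + m + 1), (m - d) / (m + d + 1),
                    (u - d) / (u + d + 1), np.log1p(m),
                    np.log1p(u) - np.log1p(m), np.log1p(m) - np.log1p(d),
                    d / (u + 1),
                ]
            assert np.allclose(out, exp)


class TestAnnotEnd:
    def region(self, stops):
        return TerminalRegion("chr1", "+", 1, 1000, ("t",), tuple(stops))

    def test_stop_inside_bin(self):
        assert annot_end_feature(201, 300, self.region([300])) == 1

    def test_stop_outside_bin(self):
        assert annot_end_feature(201, 300, self.region([301])) == -1

    def test_merged_region_multiple_stops(self):
        r = self.region([150, 850])
        flags = [annot_end_feature(s, s + 99, r) for s in range(1, 1000, 100)]
        assert flags == [-1, 1, -1, -1, -1, -1, -1, -1, 1, -1]


class TestFeaturize:
    def test_all_n_genome_gives_negative_sequence_features(self):
        genome = GenomeSequence({"chr1": "N" * 1000})
        cov = CoverageTrack({("chr1", "."): np.zeros(1000)}, stranded=False)
        r = TerminalRegion("chr1", "+", 1, 300, ("t",), (300,))
        seqs = bin_region(r, 100, 300)
        featurize(seqs, genome, cov)
        X = seqs[0].X[seqs[0].mask]
        assert (X[:, :12] == -1).all()

    def test_zero_coverage_gives_zero_rna_features(self):
        genome = GenomeSequence({"chr1": "A" * 1000})
        cov = CoverageTrack({("chr1", "."): np.zeros(1000)}, stranded=False)
        r = TerminalRegion("chr1", "+", 1, 300, ("t",), (300,))
        seqs = bin_region(r, 100, 300)
        featurize(seqs, genome, cov)
        assert np.allclose(seqs[0].X[:, RNA_SLICE], 0)

    def test_padded_bins_hold_zeros(self, small_sequences):
        for bs in small_sequences:
            assert np.allclose(bs.X[~bs.mask], 0)

    def test_vector_shape_and_binary_slots(self, small_sequences):
        for bs in small_sequences:
            assert bs.X.shape == (bs.max_len, N_FEATURES)
            real = bs.X[bs.mask]
            assert np.isin(real[:, :12], (-1, 1)).all()
            assert np.isin(real[:, 26], (-1, 1)).all()

    def test_strand_symmetry(self):
        """A region and its reverse-complement mirror featurize identically."""
        rng = np.random.default_rng(11)
        n = 2000
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        depth = rng.integers(0, 200, n).astype(float)
        g_fwd = GenomeSequence({"chr1": seq})
        c_fwd = CoverageTrack({("chr1", "."): depth}, stranded=False)
        g_rev = GenomeSequence({"chr1": reverse_complement(seq)})
        c_rev = CoverageTrack({("chr1", "."): depth[::-1]}, stranded=False)
        r_fwd = TerminalRegion("chr1", "+", 501, 1100, ("t",), (700,))
        # mirror of [501,1100] in a genome of length n: [n-1100+1, n-501+1]
        r_rev = TerminalRegion("chr1", "-", n - 1100 + 1, n - 501 + 1,
                               ("t",), (n - 700 + 1,))
        s_fwd = bin_region(r_fwd, 100, 300)
        s_rev = bin_region(r_rev, 100, 300)
        featurize(s_fwd, g_fwd, c_fwd)
        featurize(s_rev, g_rev, c_rev)
        assert np.allclose(s_fwd[0].X, s_rev[0].X)

    def test_pas_enriched_in_labeled_bins(self, small_sequences):
        X = np.concatenate([bs.X[bs.mask] for bs in small_sequences])
        y = np.concatenate([bs.labels[bs.mask] for bs in small_sequences])
        # canonical PAS positive rate higher in site bins than elsewhere
        assert (X[y == 1, 0] == 1).mean() > (X[y == 0, 0] == 1).mean()

    def test_dna_rna_independence_when_channels_independent(self):
        fx_seq = generate(SimConfig(n_transcripts=40, seed=3))
        rng = np.random.default_rng(9)
        noise_cov = CoverageTrack(
            {
                (c, s): rng.poisson(
                    50, fx_seq.genome.length(c)
                ).astype(float)
                for c in fx_seq.genome.chrom_names
                for s in ("+", "-")
            },
            stranded=True,
        )
        seqs = pipeline.build_sequences(
            fx_seq.transcripts, fx_seq.genome, noise_cov,
            truth=fx_seq.sites, merge=True,
        )
        X = np.concatenate([bs.X[bs.mask] for bs in seqs])
        worst = 0.0
        for i in range(12):
            for j in range(12, 26):
                a, b = X[:, i], X[:, j]
                if a.std() == 0 or b.std() == 0:
                    continue
                worst = max(worst, abs(np.corrcoef(a, b)[0, 1]))
        assert worst < 0.1
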