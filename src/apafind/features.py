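"""Per-bin feature engineering: 27 features from DNA sequence, read
coverage and the original annotation.

Every bin is featurized from a 300-base window in transcription
orientation — 100 bases upstream, the bin, 100 bases downstream — so
"downstream" always means 3' of transcription regardless of genomic
strand. The vector layout is frozen:

* 4 polyA-signal (PAS) hexamer indicators (canonical AATAAA, ATTAAA,
  AGTAAA, any minor variant), each in {-1, 1};
* 8 sequence-element indicators placed relative to the PAS (or a neutral
  anchor when no PAS is found), each in {-1, 1};
* 14 read-coverage contrasts (7 intra-bin over thirds of the window,
  7 inter-bin over the neighbouring bins), real-valued and finite;
* 1 annotation-end indicator: 1 iff an original transcript 3' stop falls
  in the bin.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .core import BinSequence, CoverageTrack, GenomeSequence, reverse_complement

N_FEATURES = 27
RNA_SLICE = slice(12, 26)  # the 14 standardizable coverage features

FEATURE_NAMES = (
    "pas_aataaa", "pas_attaaa", "pas_agtaaa", "pas_minor",
    "elem_g_rich_down", "elem_ttt_near_down", "elem_gt_tg_down",
    "elem_gtgt_tgtg_down", "elem_t_rich_down", "elem_t_rich_up",
    "elem_tgta_tata_up", "elem_at_rich",
    "rna_intra_s_um", "rna_intra_s_md", "rna_intra_s_ud", "rna_intra_log_m",
    "rna_intra_dlog_um", "rna_intra_dlog_md", "rna_intra_dropfrac",
    "rna_inter_s_um", "rna_inter_s_md", "rna_inter_s_ud", "rna_inter_log_m",
    "rna_inter_dlog_um", "rna_inter_dlog_md", "rna_inter_dropfrac",
    "annot_end",
)

PAS_CANONICAL = "AATAAA"
PAS_VARIANT_1 = "ATTAAA"
PAS_VARIANT_2 = "AGTAAA"
PAS_MINOR = (
    "AAGAAA", "AAAAAG", "AATACA", "TATAAA",
    "GATAAA", "AATATA", "CATAAA", "AATAGA",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Window geometry and element-enrichment thresholds (all configurable).

    The PAS scan covers window offsets ``[pas_scan_start, pas_scan_end)`` —
    by default from 35 bases upstream of the bin's 5' edge through the
    bin's 3' edge, reflecting PAS placement ~10-35 nt upstream of a
    cleavage site anywhere in the bin.
    """

    flank: int = 100
    pas_scan_start: int = 65
    pas_scan_end: int = 200
    neutral_anchor_offset: int = 15  # P = bin 5' edge + this, when no PAS
    g_rich_min: int = 3         # non-overlapping GGG in downstream region
    ttt_near_min: int = 2       # TTT in the near-downstream region
    gt_tg_min: int = 6          # overlapping GT/TG dimers downstream
    gtgt_tgtg_min: int = 2      # GTGT/TGTG downstream
    t_rich_frac: float = 0.4    # T fraction for the two T-rich indicators
    at_rich_frac: float = 0.65  # A+T fraction over upstream+downstream
    t_rich_span: int = 30

    def hash(self) -> str:
        payload = json.dumps(
            {"config": asdict(self), "order": FEATURE_NAMES}, sort_keys=True
        )
        return hashlib.sha1(payload.encode()).hexdigest()


def build_window(
    bin_start: int,
    bin_end: int,
    strand: str,
    chrom: str,
    genome: GenomeSequence,
    cov: CoverageTrack,
    flank: int = 100,
) -> tuple[str, np.ndarray]:
    """Sequence and depth over flank+bin+flank, transcription-oriented.

    Positions beyond the chromosome ends are filled with 'N' (sequence)
    and 0 (coverage).
    """
    seq = genome.fetch(chrom, bin_start - flank, bin_end + flank)
    depth = cov.window(chrom, strand, bin_start - flank, bin_end + flank)
    if strand == "-":
        seq = reverse_complement(seq)
        depth = depth[::-1]
    return seq, depth


def _count_overlapping(seq: str, motif: str) -> int:
    n, count, start = len(motif), 0, 0
    while True:
        i = seq.find(motif, start)
        if i == -1:
            return count
        count += 1
        start = i + 1


def _match_offsets(seq: str, motifs: Sequence[str], lo: int, hi: int) -> list[int]:
    """Start offsets in [lo, hi) where a motif lies fully inside [lo, hi)."""
    out = []
    for m in motifs:
        last = hi - len(m)
        start = lo
        while True:
            i = seq.find(m, start)
            if i == -1 or i > last:
                break
            out.append(i)
            start = i + 1
    return out


def scan_pas(
    window_seq: str, config: FeatureConfig = FeatureConfig()
) -> tuple[np.ndarray, int | None]:
    """Four PAS indicator features and the anchor position of the best match.

    The anchor is the highest-priority hexamer class present (canonical >
    ATTAAA > AGTAAA > minor variants), ties within a class broken 3'-most.
    """
    lo, hi = config.pas_scan_start, config.pas_scan_end
    feats = np.full(4, -1.0)
    pas_pos: int | None = None
    for rank, motifs in enumerate(
        ((PAS_CANONICAL,), (PAS_VARIANT_1,), (PAS_VARIANT_2,), PAS_MINOR)
    ):
        offsets = _match_offsets(window_seq, motifs, lo, hi)
        if offsets:
            feats[rank] = 1.0
            if pas_pos is None:
                pas_pos = max(offsets)
    return feats, pas_pos


def scan_elements(
    window_seq: str,
    pas_pos: int | None,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Eight sequence-element indicators positioned relative to the PAS.

    With anchor P (the PAS offset, or a neutral anchor just inside the bin
    when none is found): downstream D = [P+6, P+106), upstream
    U = [P-100, P), near-downstream N = [P+6, P+40), all clipped to the
    window. Each indicator is 1 iff its count or composition threshold is
    met, else -1.
    """
    L = len(window_seq)
    if pas_pos is None:
        pas_pos = config.flank + config.neutral_anchor_offset
    p = pas_pos
    D = window_seq[min(p + 6, L) : min(p + 106, L)]
    U = window_seq[max(p - 100, 0) : max(p, 0)]
    N = window_seq[min(p + 6, L) : min(p + 40, L)]

    def frac(s: str, chars: str) -> float:
        return sum(s.count(c) for c in chars) / len(s) if s else 0.0

    d_first = D[: config.t_rich_span]
    u_last = U[-config.t_rich_span :] if U else ""
    counts = np.array(
        [
            D.count("GGG") >= config.g_rich_min,
            _count_overlapping(N, "TTT") >= config.ttt_near_min,
            _count_overlapping(D, "GT") + _count_overlapping(D, "TG")
            >= config.gt_tg_min,
            _count_overlapping(D, "GTGT") + _count_overlapping(D, "TGTG")
            >= config.gtgt_tgtg_min,
            frac(d_first, "T") >= config.t_rich_frac,
            frac(u_last, "T") >= config.t_rich_frac,
            _count_overlapping(U, "TGTA") + _count_overlapping(U, "TATA")
            >= config.gtgt_tgtg_min,
            frac(U + D, "AT") >= config.at_rich_frac,
        ]
    )
    return np.where(counts, 1.0, -1.0)


def _contrasts(u: float, m: float, d: float) -> list[float]:
    """Seven bounded contrasts of upstream/middle/downstream depths."""

    def s(a: float, b: float) -> float:
        return (a - b) / (a + b + 1.0)

    def L(x: float) -> float:
        return float(np.log1p(x))

    return [
        s(u, m), s(m, d), s(u, d),
        L(m), L(u) - L(m), L(m) - L(d),
        d / (u + 1.0),
    ]


def rna_features(
    window_cov: np.ndarray,
    inter_medians: tuple[float, float, float],
    flank: int = 100,
) -> np.ndarray:
    """14 coverage features: intra-bin window thirds + inter-bin neighbours.

    Median depth is used throughout to damp local coverage spikes. The
    intra triple is (upstream flank, bin, downstream flank) of the window;
    the inter triple is (previous bin, this bin, next bin) along the
    region, zeros standing in for missing neighbours.
    """
    bw = len(window_cov) - 2 * flank
    mu = float(np.median(window_cov[:flank]))
    mm = float(np.median(window_cov[flank : flank + bw]))
    md = float(np.median(window_cov[flank + bw :]))
    out = _contrasts(mu, mm, md) + _contrasts(*inter_medians)
    return np.asarray(out, dtype=float)


def annot_end_feature(bin_start: int, bin_end: int, region) -> float:
    """1 iff any source transcript's original 3' stop lies in the bin."""
    return (
        1.0
        if any(bin_start <= stop <= bin_end for stop in region.original_stops)
        else -1.0
    )


def featurize(
    bin_sequences: Sequence[BinSequence],
    genome: GenomeSequence,
    cov: CoverageTrack,
    config: FeatureConfig = FeatureConfig(),
) -> list[BinSequence]:
    """Fill ``X`` (max_len x 27) for every sequence; padded bins stay zero."""
    for bs in bin_sequences:
        X = np.zeros((bs.max_len, N_FEATURES), dtype=float)
        n = bs.n_real
        strand_key = bs.strand
        bin_medians = np.array(
            [
                np.median(cov.window(bs.chrom, strand_key, s, e))
                for s, e in zip(bs.starts[:n], bs.ends[:n])
            ]
        )
        for i in range(n):
            seq, depth = build_window(
                int(bs.starts[i]), int(bs.ends[i]), bs.strand, bs.chrom,
                genome, cov, config.flank,
            )
            pas, pas_pos = scan_pas(seq, config)
            elems = scan_elements(seq, pas_pos, config)
            prev_m = bin_medians[i - 1] if i > 0 else 0.0
            next_m = bin_medians[i + 1] if i + 1 < n else 0.0
            rna = rna_features(
                depth, (float(prev_m), float(bin_medians[i]), float(next_m)),
                config.flank,
            )
            X[i, :4] = pas
            X[i, 4:12] = elems
            X[i, RNA_SLICE] = rna
            X[i, 26] = annot_end_feature(
                int(bs.starts[i]), int(bs.ends[i]), bs.region
            )
        bs.X = X
    return list(bin_sequences)


def feature_table(bin_sequences: Sequence[BinSequence]):
    """Per-real-bin feature matrix as a DataFrame, for TSV dumps."""
    import pandas as pd

    rows = []
    for bs in bin_sequences:
        for i in range(bs.n_real):
            row = {
                "chrom": bs.chrom,
                "start": int(bs.starts[i]),
                "end": int(bs.ends[i]),
                "strand": bs.strand,
            }
            row.update(dict(zip(FEATURE_NAMES, bs.X[i])))
            row["label"] = int(bs.labels[i]) if bs.labels is not None else -1
            rows.append(row)
    return pd.DataFrame(rows)
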