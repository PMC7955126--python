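"""Terminal-exon processing: isolate, extend, coverage-refine, merge, bin.

The unit the classifier sees is the "modified 3' terminal exon": the last
exon of each transcript, extended 10,000 bases plus twice the bin size
downstream (trimmed against same-strand neighbours), then truncated where
read coverage collapses. Regions are cut into fixed-width bins ordered
5'->3' along the transcript.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core import (
    BinSequence,
    CoverageTrack,
    PolyASiteSet,
    TerminalRegion,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

EXTENSION_BASE = 10_000


def extension_length(bin_size: int) -> int:
    """Downstream extension applied to each terminal exon (bases)."""
    return EXTENSION_BASE + 2 * bin_size


def extract_terminal_exon(t: TranscriptModel) -> TerminalRegion:
    """The transcript's last exon in transcription order, as a region."""
    start, end = t.terminal_exon
    return TerminalRegion(
        chrom=t.chrom,
        strand=t.strand,
        start=start,
        end=end,
        source_transcript_ids=(t.transcript_id,),
        original_stops=(t.stop,),
    )


def extend_region(
    r: TerminalRegion,
    bin_size: int,
    neighbors: Sequence[TranscriptModel],
    chrom_length: int,
) -> TerminalRegion:
    """Move the 3' boundary downstream by ``10000 + 2*bin_size`` bases.

    The extension is clipped at the chromosome end and shortened so it does
    not overlap the genomic span of any same-strand neighbour; it is never
    shortened past the original stop.
    """
    ext = extension_length(bin_size)
    if r.strand == "+":
        new_end = min(r.end + ext, chrom_length)
        for n in neighbors:
            s, e = n.span
            if e > r.end and s <= new_end:  # neighbour intrudes on the extension
                new_end = max(r.end, min(new_end, s - 1))
        return TerminalRegion(
            r.chrom, r.strand, r.start, new_end,
            r.source_transcript_ids, r.original_stops, r.merged,
        )
    new_start = max(r.start - ext, 1)
    for n in neighbors:
        s, e = n.span
        if s < r.start and e >= new_start:
            new_start = min(r.start, max(new_start, e + 1))
    return TerminalRegion(
        r.chrom, r.strand, new_start, r.end,
        r.source_transcript_ids, r.original_stops, r.merged,
    )


def refine_region(
    r: TerminalRegion,
    cov: CoverageTrack,
    bin_size: int,
    min_abs_cov: float = 5.0,
    frac: float = 0.05,
) -> TerminalRegion:
    """Truncate the extension where coverage collapses.

    Walking 5'->3' from the original stop in windows of ``bin_size`` bases,
    the extension is cut at the first window whose mean depth falls below
    ``max(min_abs_cov, frac * D0)``, where D0 is the mean depth over the
    window ending at the original stop. The region is never made shorter
    than the original terminal exon.
    """
    stop = r.original_stops[0]
    strand = r.strand
    if strand == "+":
        d0 = cov.window(r.chrom, strand, stop - bin_size + 1, stop).mean()
        thr = max(min_abs_cov, frac * d0)
        new_end = r.end
        pos = stop + 1
        while pos <= r.end:
            w_end = min(pos + bin_size - 1, r.end)
            if cov.window(r.chrom, strand, pos, w_end).mean() < thr:
                new_end = pos - 1
                break
            pos = w_end + 1
        return TerminalRegion(
            r.chrom, strand, r.start, new_end,
            r.source_transcript_ids, r.original_stops, r.merged,
        )
    d0 = cov.window(r.chrom, strand, stop, stop + bin_size - 1).mean()
    thr = max(min_abs_cov, frac * d0)
    new_start = r.start
    pos = stop - 1
    while pos >= r.start:
        w_start = max(pos - bin_size + 1, r.start)
        if cov.window(r.chrom, strand, w_start, pos).mean() < thr:
            new_start = pos + 1
            break
        pos = w_start - 1
    return TerminalRegion(
        r.chrom, strand, new_start, r.end,
        r.source_transcript_ids, r.original_stops, r.merged,
    )


def merge_regions(regions: Sequence[TerminalRegion]) -> list[TerminalRegion]:
    """Union same-chromosome, same-strand overlapping regions.

    Used before training so no genomic bin is duplicated; prediction keeps
    per-transcript regions.
    """
    by: dict[tuple[str, str], list[TerminalRegion]] = {}
    for r in regions:
        by.setdefault((r.chrom, r.strand), []).append(r)
    out: list[TerminalRegion] = []
    for (chrom, strand), group in by.items():
        group = sorted(group, key=lambda r: (r.start, r.end))
        cur = group[0]
        cur_ids, cur_stops, cur_end, cur_start = (
            list(cur.source_transcript_ids),
            list(cur.original_stops),
            cur.end,
            cur.start,
        )
        n_merged = 1
        for r in group[1:]:
            if r.start <= cur_end:  # overlap
                cur_end = max(cur_end, r.end)
                cur_ids.extend(r.source_transcript_ids)
                cur_stops.extend(r.original_stops)
                n_merged += 1
            else:
                out.append(
                    TerminalRegion(
                        chrom, strand, cur_start, cur_end,
                        tuple(cur_ids), tuple(cur_stops), merged=n_merged > 1,
                    )
                )
                cur_ids = list(r.source_transcript_ids)
                cur_stops = list(r.original_stops)
                cur_start, cur_end = r.start, r.end
                n_merged = 1
        out.append(
            TerminalRegion(
                chrom, strand, cur_start, cur_end,
                tuple(cur_ids), tuple(cur_stops), merged=n_merged > 1,
            )
        )
    return out


def bin_region(
    r: TerminalRegion,
    bin_size: int,
    max_len: int,
    labels: PolyASiteSet | None = None,
) -> list[BinSequence]:
    """Tile a region with ``bin_size``-wide bins, 5'->3' in transcription order.

    A trailing remnant shorter than one bin is dropped. Regions longer than
    ``max_len`` bins are split into consecutive chunks; each chunk is padded
    at its 3' tail to exactly ``max_len`` bins with masked bins.
    """
    n_bins = r.length // bin_size
    if n_bins == 0:
        logger.warning(
            "region %s:%d-%d (%s) shorter than one bin; skipped",
            r.chrom, r.start, r.end, r.strand,
        )
        return []
    if r.strand == "+":
        starts = r.start + bin_size * np.arange(n_bins)
        ends = starts + bin_size - 1
    else:
        ends = r.end - bin_size * np.arange(n_bins)
        starts = ends - bin_size + 1
    lab = None
    if labels is not None:
        lab = np.array(
            [
                1 if len(labels.in_interval(r.chrom, r.strand, s, e)) else 0
                for s, e in zip(starts, ends)
            ],
            dtype=np.int8,
        )
    out: list[BinSequence] = []
    n_chunks = (n_bins + max_len - 1) // max_len
    if n_chunks > 1:
        logger.info(
            "region %s:%d-%d split into %d chunks of %d bins",
            r.chrom, r.start, r.end, n_chunks, max_len,
        )
    for ci in range(n_chunks):
        sl = slice(ci * max_len, min((ci + 1) * max_len, n_bins))
        k = sl.stop - sl.start
        cs = np.zeros(max_len, dtype=np.int64)
        ce = np.zeros(max_len, dtype=np.int64)
        mask = np.zeros(max_len, dtype=bool)
        cs[:k], ce[:k], mask[:k] = starts[sl], ends[sl], True
        cl = None
        if lab is not None:
            cl = np.zeros(max_len, dtype=np.int8)
            cl[:k] = lab[sl]
        out.append(
            BinSequence(
                region=r, bin_size=bin_size, max_len=max_len,
                starts=cs, ends=ce, mask=mask, labels=cl, chunk_index=ci,
            )
        )
    return out
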