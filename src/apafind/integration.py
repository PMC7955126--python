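"""Turn positive bin calls into new transcript 3'-ends.

Each positive bin yields a candidate stop at the bin's 3'-most base in
transcription orientation. A candidate is suppressed when (1) the input
transcript's stop already lies inside that bin, or (2) the candidate is
within 100 bases of the input transcript's stop. Surviving candidates
become new isoforms: a copy of the source transcript with only the
terminal exon's 3' boundary moved — the intron chain is never touched —
and the originals are always emitted unchanged (the pipeline only adds
transcripts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import BinSequence, TranscriptModel
from .model import Predictions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SitePlacement:
    transcript_id: str
    new_stop: int
    bin_start: int
    bin_end: int
    probability: float


def place_sites(
    predictions: Predictions,
    sequences: Sequence[BinSequence],
    transcripts: dict[str, TranscriptModel],
    min_distance: int = 100,
) -> list[SitePlacement]:
    """Candidate new stops from positive bins of per-transcript sequences."""
    placements: list[SitePlacement] = []
    seen: set[tuple[str, int]] = set()
    calls = predictions.calls
    for row, bs in enumerate(sequences):
        (tid,) = bs.region.source_transcript_ids  # prediction is unmerged
        t = transcripts[tid]
        stop = t.stop
        for i in range(bs.n_real):
            if not calls[row, i]:
                continue
            s, e = int(bs.starts[i]), int(bs.ends[i])
            new_stop = e if bs.strand == "+" else s
            if s <= stop <= e:
                continue  # rule (1): original stop already in this bin
            if abs(new_stop - stop) <= min_distance:
                continue  # rule (2): too close to the original stop
            if (tid, new_stop) in seen:
                continue
            seen.add((tid, new_stop))
            placements.append(
                SitePlacement(
                    transcript_id=tid, new_stop=new_stop,
                    bin_start=s, bin_end=e,
                    probability=float(predictions.probs[row, i]),
                )
            )
    return placements


def _with_new_stop(t: TranscriptModel, new_stop: int) -> TranscriptModel | None:
    """Copy of t with the terminal exon's 3' boundary moved to new_stop.

    Returns None when the move would invert the terminal exon (a stop 5'
    of the exon's original start cannot be honoured without touching the
    intron chain).
    """
    exons = list(t.exons)
    if t.strand == "+":
        start, _ = exons[-1]
        if new_stop < start:
            return None
        exons[-1] = (start, new_stop)
        if len(exons) > 1 and new_stop <= exons[-2][1]:
            return None
    else:
        _, end = exons[0]
        if new_stop > end:
            return None
        exons[0] = (new_stop, end)
        if len(exons) > 1 and new_stop >= exons[1][0]:
            return None
    return TranscriptModel(
        transcript_id=t.transcript_id, gene_id=t.gene_id, chrom=t.chrom,
        strand=t.strand, exons=tuple(exons), source="predicted",
    )


def build_modified_transcriptome(
    original: Sequence[TranscriptModel],
    placements: Sequence[SitePlacement],
    dedup_across_isoforms: bool = False,
) -> list[TranscriptModel]:
    """Originals unchanged plus one new isoform per surviving placement.

    New ids are ``<source_id>.apa<k>`` with k assigned in genomic order of
    the new stop, so re-runs are stable. A placement whose resulting exon
    chain is already present in the input is skipped (this makes a second
    integration pass over an already-modified transcriptome a no-op).
    With ``dedup_across_isoforms`` a placement is also skipped when any
    input transcript of the same gene already stops at that exact position.
    """
    by_tid: dict[str, list[SitePlacement]] = {}
    for p in placements:
        by_tid.setdefault(p.transcript_id, []).append(p)
    existing_chains = {(t.chrom, t.strand, t.exons) for t in original}
    existing_stops = {(t.chrom, t.strand, t.gene_id, t.stop) for t in original}
    index = {t.transcript_id: t for t in original}
    out = list(original)
    ids = {t.transcript_id for t in original}
    for tid, plist in by_tid.items():
        t = index[tid]
        for k, p in enumerate(sorted(plist, key=lambda p: p.new_stop), start=1):
            nt = _with_new_stop(t, p.new_stop)
            if nt is None:
                logger.warning(
                    "placement %s@%d would invert the terminal exon; rejected",
                    tid, p.new_stop,
                )
                continue
            if (nt.chrom, nt.strand, nt.exons) in existing_chains:
                logger.info(
                    "placement %s@%d duplicates an existing structure; skipped",
                    tid, p.new_stop,
                )
                continue
            if dedup_across_isoforms and (
                nt.chrom, nt.strand, nt.gene_id, nt.stop
            ) in existing_stops:
                continue
            new_id = f"{tid}.apa{k}"
            if new_id in ids:
                raise ValueError(f"duplicate output transcript id {new_id}")
            ids.add(new_id)
            nt = TranscriptModel(
                transcript_id=new_id, gene_id=nt.gene_id, chrom=nt.chrom,
                strand=nt.strand, exons=nt.exons, source="predicted",
            )
            existing_chains.add((nt.chrom, nt.strand, nt.exons))
            out.append(nt)
    return out
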