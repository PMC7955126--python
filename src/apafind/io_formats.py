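"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 1-based inclusive. BED and bedGraph (0-based,
half-open) are converted here, at the boundary, and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    CoverageTrack,
    FormatError,
    GenomeSequence,
    PolyASiteSet,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

SOURCE_TAG = "apafind"


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a multi-record FASTA into memory, one record per chromosome."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise FormatError(f"duplicate FASTA header {record.id!r} in {path}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gtf(path_or_handle: str | Path | TextIO) -> list[TranscriptModel]:
    """Parse exon features of a GTF into TranscriptModels.

    Records on strand '.' are dropped with a logged count (unstranded
    contigs cannot be oriented). Exon intervals stay 1-based inclusive.
    """
    import pyranges as pr

    if hasattr(path_or_handle, "read"):
        # pyranges wants a path; buffer stdin to a temp file.
        import tempfile

        with tempfile.NamedTemporaryFile(
            "w", suffix=".gtf", delete=False
        ) as tmp:
            tmp.write(path_or_handle.read())
            path = tmp.name
    else:
        path = str(path_or_handle)

    df = pr.read_gtf(path).df
    if df.empty:
        return []
    df = df[df.Feature == "exon"].copy()
    if df.empty:
        return []
    if "transcript_id" not in df.columns or df.transcript_id.isna().any():
        raise FormatError(f"{path}: exon feature without transcript_id attribute")
    n_unstranded = int((df.Strand == ".").sum())
    if n_unstranded:
        logger.info("dropping %d unstranded exon records", n_unstranded)
        df = df[df.Strand != "."]
    # pyranges converts GTF starts to 0-based; convert back.
    df["Start"] = df.Start + 1
    transcripts = []
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("Start")
        gene_id = grp.gene_id.iloc[0] if "gene_id" in grp.columns else tid
        source = "original"
        if "source_tag" in grp.columns and grp.source_tag.notna().iloc[0]:
            source = "predicted"
        transcripts.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(gene_id) if pd.notna(gene_id) else str(tid),
                chrom=str(grp.Chromosome.iloc[0]),
                strand=str(grp.Strand.iloc[0]),
                exons=tuple((int(s), int(e)) for s, e in zip(grp.Start, grp.End)),
                source=source,
            )
        )
    return transcripts


def write_gtf(
    transcripts: Sequence[TranscriptModel], path_or_handle: str | Path | TextIO
) -> None:
    """Write transcript and exon lines; predicted transcripts are tagged.

    Coordinates are written unchanged (1-based inclusive). Predicted
    transcripts carry the attribute ``source_tag`` so they can be told apart
    from the original annotation after a round-trip.
    """

    def _emit(fh: TextIO) -> None:
        fh.write(f"##gtf produced by {SOURCE_TAG}\n")
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.source == "predicted":
                attrs += f' source_tag "{SOURCE_TAG}";'
            span = t.span
            fh.write(
                f"{t.chrom}\t{SOURCE_TAG}\ttranscript\t{span[0]}\t{span[1]}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for start, end in t.exons:
                fh.write(
                    f"{t.chrom}\t{SOURCE_TAG}\texon\t{start}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )

    if hasattr(path_or_handle, "write"):
        _emit(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _emit(fh)


def _read_bedgraph_arrays(
    path: str | Path, chrom_lengths: dict[str, int] | None
) -> dict[str, np.ndarray]:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df.chrom.str.startswith("track")]
    arrays: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        n = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(grp.end.max())
        )
        arr = np.zeros(n, dtype=float)
        for s, e, v in zip(grp.start, grp.end, grp.value):
            # bedGraph is 0-based half-open: [s, e) covers 1-based s+1..e
            arr[int(s) : int(e)] = float(v)
        arrays[chrom] = arr
    return arrays


def _bam_coverage(path: str | Path) -> dict[str, np.ndarray]:
    """Split-aware per-base coverage from a sorted, indexed BAM.

    Counts each aligned base of each read segment once; N-CIGAR gaps
    contribute nothing (bedtools genomecov -split semantics). Secondary and
    supplementary alignments are excluded; duplicates are kept.
    """
    import pysam

    def keep(read) -> bool:
        return not (read.is_unmapped or read.is_secondary or read.is_supplementary)

    arrays: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if not bam.has_index():
            raise FormatError(f"{path}: BAM must be coordinate-sorted and indexed")
        for ref, length in zip(bam.references, bam.lengths):
            a, c, g, t = bam.count_coverage(
                ref, quality_threshold=0, read_callback=keep
            )
            arrays[ref] = (
                np.asarray(a, dtype=float)
                + np.asarray(c)
                + np.asarray(g)
                + np.asarray(t)
            )
    return arrays


def load_coverage(
    path: str | Path,
    stranded: bool = False,
    minus_path: str | Path | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> CoverageTrack:
    """Build a CoverageTrack from a BAM or bedGraph.

    For stranded coverage pass two bedGraphs (``path`` = plus strand,
    ``minus_path`` = minus strand). BAM input yields unstranded coverage.
    """
    is_bam = str(path).endswith(".bam")
    if stranded:
        if is_bam or minus_path is None:
            raise FormatError(
                "stranded coverage needs a plus/minus bedGraph pair; "
                "for a single BAM or bedGraph use stranded=False"
            )
        plus = _read_bedgraph_arrays(path, chrom_lengths)
        minus = _read_bedgraph_arrays(minus_path, chrom_lengths)
        data = {(c, "+"): arr for c, arr in plus.items()}
        for c, arr in minus.items():
            if (c, "+") in data and len(arr) != len(data[(c, "+")]):
                n = max(len(arr), len(data[(c, "+")]))
                data[(c, "+")] = np.pad(data[(c, "+")], (0, n - len(data[(c, "+")])))
                arr = np.pad(arr, (0, n - len(arr)))
            data[(c, "-")] = arr
        # chromosomes present on one strand only still need both keys
        for (c, s) in list(data):
            other = "-" if s == "+" else "+"
            data.setdefault((c, other), np.zeros_like(data[(c, s)]))
        return CoverageTrack(data, stranded=True)
    arrays = _bam_coverage(path) if is_bam else _read_bedgraph_arrays(path, chrom_lengths)
    return CoverageTrack({(c, "."): arr for c, arr in arrays.items()}, stranded=False)


def read_polya_bed(path: str | Path) -> PolyASiteSet:
    """Read a BED6-like file of polyA sites.

    The cleavage position is the interval's 3' base on the site's strand:
    BED ``end`` on '+', ``start + 1`` on '-' (identical for single-base
    records). The strand column is mandatory — labels must be stranded.
    """
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, dtype={0: str}
    )
    if df.shape[1] < 6:
        raise FormatError(
            f"{path}: polyA site file needs 6 BED columns including strand"
        )
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    if not df.strand.isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand column must be '+' or '-' on every line")
    pos = np.where(df.strand == "+", df.end, df.start + 1)
    return PolyASiteSet(zip(df.chrom, df.strand, pos.astype(int)))


def write_polya_bed(sites: PolyASiteSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, strand, pos) in enumerate(sites):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\tsite{i}\t0\t{strand}\n")


def write_bedgraph(
    arrays: dict[str, np.ndarray], path: str | Path
) -> None:
    """Run-length encode per-chromosome depth arrays to bedGraph."""
    with open(path, "w") as fh:
        for chrom, arr in arrays.items():
            arr = np.asarray(arr)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    v_out = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v_out}\n")


def write_regions_bed(regions: Iterable, path: str | Path) -> None:
    """Debug dump of terminal regions for genome-browser inspection."""
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(r.source_transcript_ids)
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t0\t{r.strand}\n")
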