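"""Core domain types shared across the pipeline.

All coordinates are 1-based inclusive (GTF convention). Conversion from
0-based/half-open formats (BED, bedGraph) happens only in the readers and
writers in :mod:`apafind.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: its exon chain, strand and identifiers.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals sorted by
    genomic coordinate and non-overlapping. The transcript's 3' stop is the
    last base of the last exon on ``+`` and the first base of the first exon
    on ``-``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "original"  # "original" | "predicted"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon start {start} > end {end}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = end

    @property
    def stop(self) -> int:
        """3'-most base of the transcript in transcription order."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent: start of first exon to end of last exon."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def terminal_exon(self) -> tuple[int, int]:
        """Last exon in transcription order (first genomic exon on ``-``)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]


class GenomeSequence:
    """In-memory genome with uppercase sequences, keyed by chromosome."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name}: invalid characters {sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice; positions outside the chromosome are 'N'."""
        n = self.length(chrom)
        lo, hi = max(start, 1), min(end, n)
        core = self._seqs[chrom][lo - 1 : hi] if lo <= hi else ""
        return "N" * (lo - start) + core + "N" * (end - hi)


class CoverageTrack:
    """Per-base read depth, optionally per strand.

    Backed by one numpy array per (chromosome, strand). For unstranded
    tracks both strand queries return the same values.
    """

    def __init__(self, data: dict[tuple[str, str], np.ndarray], stranded: bool):
        self.stranded = stranded
        self._data = {k: np.asarray(v) for k, v in data.items()}
        for arr in self._data.values():
            if (arr < 0).any():
                raise ValueError("negative depth in coverage track")

    def _array(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand) if self.stranded else (chrom, ".")
        if key not in self._data:
            raise KeyError(f"no coverage for chromosome {chrom} strand {strand}")
        return self._data[key]

    def chrom_length(self, chrom: str) -> int:
        for (c, _s), arr in self._data.items():
            if c == chrom:
                return len(arr)
        raise KeyError(chrom)

    def depth(self, chrom: str, strand: str, pos: int) -> int:
        arr = self._array(chrom, strand)
        if not 1 <= pos <= len(arr):
            raise IndexError(f"position {pos} outside {chrom} (1..{len(arr)})")
        return int(arr[pos - 1])

    def window(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """1-based inclusive depth slice, zero-filled beyond chromosome ends."""
        arr = self._array(chrom, strand)
        n = len(arr)
        out = np.zeros(end - start + 1, dtype=float)
        lo, hi = max(start, 1), min(end, n)
        if lo <= hi:
            out[lo - start : hi - start + 1] = arr[lo - 1 : hi]
        return out


class PolyASiteSet:
    """Deduplicated set of stranded cleavage positions with interval queries."""

    def __init__(self, sites: Iterable[tuple[str, str, int]]):
        self._sites = set()
        for chrom, strand, pos in sites:
            if strand not in ("+", "-"):
                raise ValueError(f"site strand must be '+' or '-', got {strand!r}")
            self._sites.add((chrom, strand, int(pos)))
        by: dict[tuple[str, str], list[int]] = {}
        for chrom, strand, pos in self._sites:
            by.setdefault((chrom, strand), []).append(pos)
        self._sorted = {k: np.array(sorted(v)) for k, v in by.items()}

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        return iter(sorted(self._sites))

    def __contains__(self, site: tuple[str, str, int]) -> bool:
        return site in self._sites

    def in_interval(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Positions of sites on (chrom, strand) within [start, end]."""
        arr = self._sorted.get((chrom, strand))
        if arr is None:
            return np.array([], dtype=int)
        lo = np.searchsorted(arr, start, side="left")
        hi = np.searchsorted(arr, end, side="right")
        return arr[lo:hi]

    def nearest_distance(self, chrom: str, strand: str, pos: int) -> int | None:
        """Distance in bases to the nearest site on the same chrom/strand."""
        arr = self._sorted.get((chrom, strand))
        if arr is None or len(arr) == 0:
            return None
        i = np.searchsorted(arr, pos)
        cands = arr[max(i - 1, 0) : i + 1]
        return int(np.abs(cands - pos).min())


@dataclass(frozen=True)
class TerminalRegion:
    """A (possibly merged) modified 3' terminal exon interval."""

    chrom: str
    strand: str
    start: int
    end: int
    source_transcript_ids: tuple[str, ...]
    original_stops: tuple[int, ...]
    merged: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        for stop in self.original_stops:
            if not self.start <= stop <= self.end:
                raise ValueError(
                    f"original stop {stop} outside region "
                    f"[{self.start},{self.end}]"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        """5' boundary in transcription order."""
        return self.start if self.strand == "+" else self.end


@dataclass
class BinSequence:
    """Fixed-width bins tiling a terminal region, 5'->3' in transcription order.

    Parallel arrays of length ``max_len``; ``mask`` marks real bins (padded
    tail bins are False and carry zero features). ``starts``/``ends`` are
    genomic 1-based inclusive bin boundaries (0 for padded bins). ``labels``
    is None until truth sites are attached; ``X`` is None until featurized.
    """

    region: TerminalRegion
    bin_size: int
    max_len: int
    starts: np.ndarray
    ends: np.ndarray
    mask: np.ndarray
    labels: np.ndarray | None = None
    X: np.ndarray | None = None
    chunk_index: int = 0

    @property
    def n_real(self) -> int:
        return int(self.mask.sum())

    @property
    def chrom(self) -> str:
        return self.region.chrom

    @property
    def strand(self) -> str:
        return self.region.strand
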