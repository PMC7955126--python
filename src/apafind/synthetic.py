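"""Desk-scale synthetic fixtures with the statistical structure the
method assumes.

The generator emits a genome, a transcript annotation, a truth set of
polyA sites and stranded coverage tracks that are mutually consistent:

* background sequence is i.i.d. uniform ACGT;
* each transcript carries 1-3 polyA sites in (or downstream of) its
  terminal exon, each with a polyA-signal hexamer planted 10-35 nt
  upstream and, with configurable probability, GU-rich and U-rich
  elements planted downstream — the positional grammar the DNA features
  encode;
* coverage along the terminal exon is a staircase proportional to the
  summed usage of the sites still downstream of each base, with an
  optional linear ramp at each drop, a read-through tail past the last
  site (precursor-mRNA reads), and optional per-base Poisson noise;
* the annotated transcript stop sits at the first (most 5') site, up to a
  small jitter, so downstream sites are invisible to the input
  annotation — exactly the situation the classifier is meant to fix.

Everything is deterministic under the config seed, and a JSON-able
manifest records what was planted where.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    CoverageTrack,
    GenomeSequence,
    PolyASiteSet,
    TranscriptModel,
    reverse_complement,
)
from .features import PAS_CANONICAL, PAS_MINOR, PAS_VARIANT_1, PAS_VARIANT_2
from .io_formats import write_bedgraph, write_fasta, write_gtf, write_polya_bed

ALL_PAS = (PAS_CANONICAL, PAS_VARIANT_1, PAS_VARIANT_2) + PAS_MINOR


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture."""

    n_chrom: int = 2
    n_transcripts: int = 200
    spacing: int = 9_000            # anchor-to-anchor distance per strand lane
    margin: int = 2_000
    exon1_length: int = 400
    intron_length: int = 300
    sites_per_transcript_probs: tuple[float, ...] = (0.3, 0.4, 0.3)  # P(1),P(2),P(3)
    first_site_range: tuple[int, int] = (400, 900)   # nt downstream of exon start
    site_gap_range: tuple[int, int] = (500, 1_200)
    pas_offset_range: tuple[int, int] = (10, 35)     # nt upstream of the site
    hexamer_probs: tuple[float, float, float, float] = (0.70, 0.15, 0.10, 0.05)
    element_gu_prob: float = 0.7
    element_t_prob: float = 0.7
    usage_decay: float = 0.6        # relative usage of each successive site
    read_depth: float = 100.0       # expected depth at the terminal exon 5' end
    readthrough_fraction: float = 0.10
    readthrough_length: int = 600
    ramp_length: int = 50           # linear drop width at each site (0 = sharp)
    intron_coverage_fraction: float = 0.05
    annot_jitter: int = 20          # annotated stop = first site +/- jitter
    noise: str = "poisson"          # "poisson" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.sites_per_transcript_probs)
        if probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("sites_per_transcript_probs must be a distribution")
        if not 10 <= self.pas_offset_range[0] <= self.pas_offset_range[1] <= 35:
            raise ValueError("pas_offset_range must lie within [10, 35]")
        if self.site_gap_range[0] < 200:
            raise ValueError(
                "sites too dense for bin separation: site gaps must be >= 200"
            )
        if self.first_site_range[0] < 100:
            raise ValueError("first site must be >= 100 nt into the terminal exon")


@dataclass
class SimFixture:
    """In-memory fixture plus the manifest of everything planted."""

    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    sites: PolyASiteSet
    coverage: CoverageTrack
    manifest: dict
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "bed": outdir / "truth_sites.bed",
            "bedgraph_plus": outdir / "coverage.plus.bedgraph",
            "bedgraph_minus": outdir / "coverage.minus.bedgraph",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(self.genome, paths["fasta"])
        write_gtf(self.transcripts, paths["gtf"])
        write_polya_bed(self.sites, paths["bed"])
        plus = {
            c: self.coverage.window(c, "+", 1, self.coverage.chrom_length(c))
            for c in self.genome.chrom_names
        }
        minus = {
            c: self.coverage.window(c, "-", 1, self.coverage.chrom_length(c))
            for c in self.genome.chrom_names
        }
        write_bedgraph(plus, paths["bedgraph_plus"])
        write_bedgraph(minus, paths["bedgraph_minus"])
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1))
        return paths


_BASES = np.array(list("ACGT"))


def _depth_profile(cfg: SimConfig, site_offsets: list[int], usages: list[float],
                   total_len: int) -> np.ndarray:
    """Expected depth over transcription offsets 0..total_len-1."""
    d = np.zeros(total_len)
    e1, intr = cfg.exon1_length, cfg.intron_length
    d[:e1] = cfg.read_depth
    d[e1 : e1 + intr] = cfg.read_depth * cfg.intron_coverage_fraction
    s0 = e1 + intr
    remaining = 1.0
    prev = s0
    for off, u in zip(site_offsets, usages):
        d[prev : s0 + off + 1] = cfg.read_depth * remaining
        remaining -= u
        prev = s0 + off + 1
    tail = cfg.read_depth * cfg.readthrough_fraction
    t0 = prev
    t1 = min(t0 + cfg.readthrough_length, total_len)
    d[t0:t1] = np.linspace(tail, 0.0, t1 - t0, endpoint=False)
    if cfg.ramp_length > 1:
        # smooth the drop-offs along the terminal exon and tail only
        seg = d[s0:t1]
        kernel = np.ones(cfg.ramp_length) / cfg.ramp_length
        d[s0:t1] = np.convolve(seg, kernel, mode="same")
    return d


def generate(cfg: SimConfig) -> SimFixture:
    """Build a fully consistent fixture; byte-identical under the same seed."""
    rng = np.random.default_rng(cfg.seed)
    lanes = cfg.n_chrom * 2
    per_lane = int(np.ceil(cfg.n_transcripts / lanes))
    chrom_len = 2 * cfg.margin + per_lane * cfg.spacing
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]

    seqs = {
        c: _BASES[rng.integers(0, 4, size=chrom_len)] for c in chrom_names
    }
    depth = {
        (c, s): np.zeros(chrom_len) for c in chrom_names for s in ("+", "-")
    }

    def plant(chrom: str, g_start: int, motif: str, strand: str) -> None:
        bases = motif if strand == "+" else reverse_complement(motif)
        seqs[chrom][g_start - 1 : g_start - 1 + len(bases)] = list(bases)

    transcripts: list[TranscriptModel] = []
    site_list: list[tuple[str, str, int]] = []
    manifest_tx = []
    n_made = 0
    for chrom in chrom_names:
        for strand in ("+", "-"):
            lane_shift = 0 if strand == "+" else cfg.spacing // 2
            for j in range(per_lane):
                if n_made >= cfg.n_transcripts:
                    break
                n_made += 1
                anchor = cfg.margin + j * cfg.spacing + lane_shift
                n_sites = 1 + rng.choice(
                    len(cfg.sites_per_transcript_probs),
                    p=cfg.sites_per_transcript_probs,
                )
                offs = [int(rng.integers(*cfg.first_site_range))]
                for _ in range(n_sites - 1):
                    offs.append(offs[-1] + int(rng.integers(*cfg.site_gap_range)))
                raw = cfg.usage_decay ** np.arange(n_sites)
                usages = (raw / raw.sum()).tolist()
                total_len = (
                    cfg.exon1_length + cfg.intron_length + offs[-1]
                    + cfg.readthrough_length + 200
                )
                s0_off = cfg.exon1_length + cfg.intron_length

                def to_genomic(t_off: int) -> int:
                    # transcription offset -> 1-based genomic position
                    if strand == "+":
                        return anchor + t_off
                    return anchor + total_len - 1 - t_off

                sites_g = [to_genomic(s0_off + o) for o in offs]
                jit = int(rng.integers(-cfg.annot_jitter, cfg.annot_jitter + 1))
                stop_off = s0_off + offs[0] + jit
                # exon boundaries in transcription offsets
                e1 = (0, cfg.exon1_length - 1)
                term = (s0_off, stop_off)
                ex_g = sorted(
                    (
                        tuple(sorted((to_genomic(e1[0]), to_genomic(e1[1])))),
                        tuple(sorted((to_genomic(term[0]), to_genomic(term[1])))),
                    )
                )
                tid = f"tx_{chrom}_{strand}_{j}"
                transcripts.append(
                    TranscriptModel(
                        transcript_id=tid, gene_id=f"g_{chrom}_{strand}_{j}",
                        chrom=chrom, strand=strand,
                        exons=tuple((int(a), int(b)) for a, b in ex_g),
                    )
                )
                site_info = []
                for o, u, pg in zip(offs, usages, sites_g):
                    site_list.append((chrom, strand, pg))
                    hx_class = rng.choice(4, p=cfg.hexamer_probs)
                    hexamer = (
                        PAS_CANONICAL, PAS_VARIANT_1, PAS_VARIANT_2,
                        PAS_MINOR[rng.integers(len(PAS_MINOR))],
                    )[hx_class]
                    pas_off = int(rng.integers(*cfg.pas_offset_range))
                    if strand == "+":
                        plant(chrom, pg - pas_off - 5, hexamer, "+")
                    else:
                        plant(chrom, pg + pas_off, hexamer, "-")
                    elements = []
                    if rng.random() < cfg.element_gu_prob:
                        m = "TGTGTGTGTGTGTG"
                        gs = pg + 8 if strand == "+" else pg - 8 - len(m) + 1
                        plant(chrom, gs, m, strand)
                        elements.append("gu_rich")
                    if rng.random() < cfg.element_t_prob:
                        m = "TTTTTTTTTT"
                        gs = pg + 24 if strand == "+" else pg - 24 - len(m) + 1
                        plant(chrom, gs, m, strand)
                        elements.append("t_rich")
                    site_info.append(
                        {
                            "pos": int(pg), "usage": float(u),
                            "hexamer": str(hexamer), "pas_offset": pas_off,
                            "elements": elements,
                        }
                    )
                prof = _depth_profile(cfg, offs, usages, total_len)
                if strand == "+":
                    depth[(chrom, "+")][anchor - 1 : anchor - 1 + total_len] += prof
                else:
                    depth[(chrom, "-")][
                        anchor - 1 : anchor - 1 + total_len
                    ] += prof[::-1]
                manifest_tx.append(
                    {
                        "transcript_id": tid, "chrom": chrom, "strand": strand,
                        "exons": [list(map(int, e)) for e in ex_g],
                        "annotated_stop": int(to_genomic(stop_off)),
                        "sites": site_info,
                    }
                )

    if cfg.noise == "poisson":
        noise_rng = np.random.default_rng(cfg.seed + 10_007)
        for key in depth:
            depth[key] = noise_rng.poisson(depth[key]).astype(float)

    genome = GenomeSequence({c: "".join(seqs[c]) for c in chrom_names})
    manifest = {
        "config": asdict(cfg),
        "n_transcripts": len(transcripts),
        "n_sites": len(set(site_list)),
        "chrom_lengths": {c: chrom_len for c in chrom_names},
        "transcripts": manifest_tx,
    }
    return SimFixture(
        genome=genome,
        transcripts=transcripts,
        sites=PolyASiteSet(site_list),
        coverage=CoverageTrack(depth, stranded=True),
        manifest=manifest,
        config=cfg,
    )


def degrade(
    fixture: SimFixture,
    shuffle_labels: bool = False,
    zero_coverage: bool = False,
    strip_pas: bool = False,
    seed: int = 0,
) -> SimFixture:
    """Controlled corruption, each knob isolating one information channel.

    ``shuffle_labels`` replaces every truth site with a uniformly random
    position inside the same transcript's covered terminal span (label
    count preserved, association destroyed); ``zero_coverage`` blanks the
    coverage track; ``strip_pas`` rewrites every polyA-signal hexamer
    occurrence on either genome strand so no DNA signal remains. No knobs
    set returns an equivalent fixture.
    """
    rng = np.random.default_rng(seed)
    genome = fixture.genome
    coverage = fixture.coverage
    sites = fixture.sites
    manifest = json.loads(json.dumps(fixture.manifest))

    if strip_pas:
        motifs = set(ALL_PAS) | {reverse_complement(m) for m in ALL_PAS}
        new_seqs = {}
        for chrom in genome.chrom_names:
            seq = genome.sequence(chrom)
            for _ in range(6):  # iterate: replacements could abut old text
                hit = False
                for m in motifs:
                    i = seq.find(m)
                    while i != -1:
                        hit = True
                        seq = seq[:i] + "CGCGCG" + seq[i + 6 :]
                        i = seq.find(m, i + 1)
                if not hit:
                    break
            new_seqs[chrom] = seq
        genome = GenomeSequence(new_seqs)
        manifest["degraded_strip_pas"] = True

    if zero_coverage:
        data = {
            (c, s): np.zeros(coverage.chrom_length(c))
            for c in genome.chrom_names
            for s in ("+", "-")
        }
        coverage = CoverageTrack(data, stranded=True)
        manifest["degraded_zero_coverage"] = True

    if shuffle_labels:
        new_sites = []
        for tx in manifest["transcripts"]:
            term_start, term_end = tx["exons"][-1] if tx["strand"] == "+" else tx["exons"][0]
            last = max(s["pos"] for s in tx["sites"])
            if tx["strand"] == "+":
                lo, hi = term_start + 50, max(last, term_end)
            else:
                lo, hi = min(last, term_start), term_end - 50
            for s in tx["sites"]:
                s["pos"] = int(rng.integers(lo, hi + 1))
                new_sites.append((tx["chrom"], tx["strand"], s["pos"]))
        sites = PolyASiteSet(new_sites)
        manifest["degraded_shuffle_labels"] = True

    return SimFixture(
        genome=genome,
        transcripts=list(fixture.transcripts),
        sites=sites,
        coverage=coverage,
        manifest=manifest,
        config=fixture.config,
    )


def shuffle_sequence_labels(sequences: Sequence, seed: int = 0) -> list:
    """Permute the real-bin labels across all sequences (null model)."""
    rng = np.random.default_rng(seed)
    flat = np.concatenate([bs.labels[bs.mask] for bs in sequences])
    perm = rng.permutation(flat)
    out = []
    pos = 0
    for bs in sequences:
        n = bs.n_real
        labels = np.zeros(bs.max_len, dtype=np.int8)
        labels[:n] = perm[pos : pos + n]
        pos += n
        out.append(replace_labels(bs, labels))
    return out


def replace_labels(bs, labels):
    from .core import BinSequence

    return BinSequence(
        region=bs.region, bin_size=bs.bin_size, max_len=bs.max_len,
        starts=bs.starts, ends=bs.ends, mask=bs.mask,
        labels=labels, X=bs.X, chunk_index=bs.chunk_index,
    )
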