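"""End-to-end orchestration: raw inputs -> bin sequences -> model -> GTF.

Two flows share the processing front end:

* training: per-transcript terminal regions are extended, refined, merged
  (so no genomic bin is duplicated), binned with truth labels, featurized,
  split 60/20/20 at the region level, standardized on the training split
  and fed to the classifier; the test split yields the evaluation report.
* prediction: regions are kept per transcript (not merged), binned without
  labels, featurized, scored by the trained model, and positive bins are
  integrated into the output transcriptome as added isoforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import CoverageTrack, GenomeSequence, PolyASiteSet, TranscriptModel
from .evaluation import EvalReport
from .features import FeatureConfig, featurize
from .integration import SitePlacement, build_modified_transcriptome, place_sites
from .model import (
    ModelConfig,
    Predictions,
    TrainedModel,
    check_feature_config,
    predict,
    split_data,
    standardize,
    train,
)
from .regions import (
    bin_region,
    extend_region,
    extract_terminal_exon,
    merge_regions,
    refine_region,
)

logger = logging.getLogger(__name__)


@dataclass
class RefineParams:
    min_abs_cov: float = 5.0
    frac: float = 0.05


def build_regions(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    coverage: CoverageTrack,
    bin_size: int = 100,
    refine_params: RefineParams = RefineParams(),
    merge: bool = False,
):
    """Modified 3' terminal exons for every transcript.

    Extension is trimmed against same-strand neighbours and the result is
    truncated where coverage collapses. With ``merge`` overlapping regions
    are unioned (training); otherwise one region per transcript.
    """
    by_lane: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_lane.setdefault((t.chrom, t.strand), []).append(t)
    regions = []
    for (chrom, strand), lane in by_lane.items():
        chrom_length = genome.length(chrom)
        for t in lane:
            r = extract_terminal_exon(t)
            neighbors = [n for n in lane if n.transcript_id != t.transcript_id]
            r = extend_region(r, bin_size, neighbors, chrom_length)
            r = refine_region(
                r, coverage, bin_size,
                min_abs_cov=refine_params.min_abs_cov, frac=refine_params.frac,
            )
            regions.append(r)
    if merge:
        regions = merge_regions(regions)
    return regions


def build_sequences(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    coverage: CoverageTrack,
    truth: PolyASiteSet | None = None,
    bin_size: int = 100,
    max_len: int = 300,
    merge: bool = False,
    refine_params: RefineParams = RefineParams(),
    feature_config: FeatureConfig = FeatureConfig(),
):
    """Binned, labeled (when truth given) and featurized sequences."""
    regions = build_regions(
        transcripts, genome, coverage, bin_size, refine_params, merge=merge
    )
    sequences = []
    for r in regions:
        sequences.extend(bin_region(r, bin_size, max_len, labels=truth))
    featurize(sequences, genome, coverage, feature_config)
    logger.info(
        "built %d sequences (%d regions, %d real bins)",
        len(sequences), len(regions), sum(bs.n_real for bs in sequences),
    )
    return sequences


def fit(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    coverage: CoverageTrack,
    truth: PolyASiteSet,
    model_config: ModelConfig = ModelConfig(),
    refine_params: RefineParams = RefineParams(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> tuple[TrainedModel, EvalReport]:
    """Train on merged labeled regions; report metrics on the test split."""
    sequences = build_sequences(
        transcripts, genome, coverage, truth=truth,
        bin_size=model_config.bin_size, max_len=model_config.max_len,
        merge=True, refine_params=refine_params, feature_config=feature_config,
    )
    tr, va, te = split_data(
        sequences, model_config.split_fractions, model_config.seed
    )
    tr_std, stats = standardize(tr)
    va_std, _ = standardize(va, stats)
    te_std, _ = standardize(te, stats)
    model = train(
        tr_std, va_std, model_config,
        standardization=stats, feature_config=feature_config,
    )
    preds = predict(model, te_std, prestandardized=True)
    import numpy as np

    labels = np.stack([bs.labels for bs in te_std])
    report = EvalReport.from_predictions(preds, labels)
    return model, report


def predict_transcriptome(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    coverage: CoverageTrack,
    model: TrainedModel,
    threshold: float | None = None,
    refine_params: RefineParams = RefineParams(),
    feature_config: FeatureConfig = FeatureConfig(),
    dedup_across_isoforms: bool = False,
) -> tuple[list[TranscriptModel], list[SitePlacement], Predictions]:
    """Score per-transcript regions and add predicted isoforms to the GTF."""
    check_feature_config(model, feature_config)
    sequences = build_sequences(
        transcripts, genome, coverage, truth=None,
        bin_size=model.bin_size, max_len=model.max_len,
        merge=False, refine_params=refine_params, feature_config=feature_config,
    )
    preds = predict(model, sequences, threshold=threshold)
    index = {t.transcript_id: t for t in transcripts}
    placements = place_sites(preds, sequences, index, min_distance=100)
    modified = build_modified_transcriptome(
        transcripts, placements, dedup_across_isoforms=dedup_across_isoforms
    )
    logger.info(
        "added %d isoforms (%d placements) to %d original transcripts",
        len(modified) - len(transcripts), len(placements), len(transcripts),
    )
    return modified, placements, preds
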