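"""Bin-level classification metrics and transcript-terminus benchmarking.

Precision P = Tp/(Tp+Fp), recall R = Tp/(Tp+Fn) and F = 2PR/(P+R) are
computed at a fixed probability threshold over real bins only, with the
0/0 convention of 0. Average precision summarizes the precision-recall
curve over all attained thresholds, AP = sum_n (R_n - R_{n-1}) P_n with
R_0 = 0 and no interpolation — the appropriate summary for a task where
bins with a polyA site are rare.

Terminus benchmarking asks, for each transcript, whether a true polyA
site lies within a base cutoff (default +/-100, inclusive) of its 3'
stop on the same chromosome and strand.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .core import PolyASiteSet, TranscriptModel


def confusion(
    calls: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> tuple[int, int, int, int]:
    """(Tp, Fp, Fn, Tn) over real bins only."""
    calls, labels, mask = (np.asarray(a) for a in (calls, labels, mask))
    if not calls.shape == labels.shape == mask.shape:
        raise ValueError("calls, labels and mask must have identical shape")
    m = mask.astype(bool)
    c = calls[m].astype(bool)
    y = labels[m].astype(bool)
    tp = int((c & y).sum())
    fp = int((c & ~y).sum())
    fn = int((~c & y).sum())
    tn = int((~c & ~y).sum())
    return tp, fp, fn, tn


def prf(counts: tuple[int, int, int, int] | tuple[int, int, int]) -> tuple[float, float, float]:
    """Precision, recall and F-measure from confusion counts; 0/0 -> 0."""
    tp, fp, fn = counts[0], counts[1], counts[2]
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of a printed precision/recall pair."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def average_precision(
    probs: np.ndarray, labels: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Step-sum average precision over the attained thresholds (descending)."""
    probs, labels = np.asarray(probs, float), np.asarray(labels)
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        probs, labels = probs[m], labels[m]
    y = labels.astype(bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positive labels")
    order = np.argsort(-probs, kind="stable")
    p_sorted = probs[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    pred_cum = np.arange(1, len(y_sorted) + 1)
    # threshold boundaries: last index of each distinct probability
    boundary = np.flatnonzero(np.diff(p_sorted) != 0)
    idx = np.concatenate([boundary, [len(p_sorted) - 1]])
    P = tp_cum[idx] / pred_cum[idx]
    R = tp_cum[idx] / n_pos
    return float(np.sum((R - np.concatenate([[0.0], R[:-1]])) * P))


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_measure: float
    average_precision: float
    threshold: float
    n_real_bins: int
    prevalence: float

    @classmethod
    def from_predictions(cls, predictions, labels: np.ndarray) -> "EvalReport":
        mask = predictions.mask
        tp, fp, fn, tn = confusion(predictions.calls, labels, mask)
        p, r, f = prf((tp, fp, fn, tn))
        ap = average_precision(predictions.probs, labels, mask)
        n = int(mask.sum())
        return cls(
            tp=tp, fp=fp, fn=fn, tn=tn,
            precision=p, recall=r, f_measure=f, average_precision=ap,
            threshold=predictions.threshold, n_real_bins=n,
            prevalence=float(np.asarray(labels)[mask].sum() / n),
        )

    def to_json(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        return (
            f"bins={self.n_real_bins} prevalence={self.prevalence:.4f} "
            f"Tp={self.tp} Fp={self.fp} Fn={self.fn} Tn={self.tn}\n"
            f"P={self.precision:.3f} R={self.recall:.3f} "
            f"F={self.f_measure:.3f} AP={self.average_precision:.3f} "
            f"@threshold={self.threshold}"
        )


@dataclass
class TerminusBenchmark:
    """Transcript 3'-terminus agreement with a true polyA-site set."""

    cutoff: int
    tp_transcripts: int
    fp_transcripts: int
    ppv: float
    unique_true_sites_captured: int
    tp_unique_termini: int
    fp_unique_termini: int
    ppv_unique_termini: float

    @property
    def n_evaluated(self) -> int:
        return self.tp_transcripts + self.fp_transcripts

    def to_json(self) -> dict:
        return asdict(self)


def ppv_percent(tp: int, total: int) -> float:
    """Positive predictive value as a percentage of evaluated items."""
    return 100.0 * tp / total if total else 0.0


def benchmark_termini(
    transcripts: Sequence[TranscriptModel],
    truth: PolyASiteSet,
    cutoff: int = 100,
) -> TerminusBenchmark:
    """Match each transcript's 3' stop against truth sites within ±cutoff.

    A transcript is a true positive iff some truth site on the same
    chromosome and strand lies within the inclusive cutoff of its stop.
    ``unique_true_sites_captured`` counts distinct truth sites matched by
    at least one transcript. Counts over distinct (chrom, strand, stop)
    termini are reported alongside the per-transcript counts.
    """
    tp = fp = 0
    captured: set[tuple[str, str, int]] = set()
    termini: dict[tuple[str, str, int], bool] = {}
    for t in transcripts:
        hits = truth.in_interval(t.chrom, t.strand, t.stop - cutoff, t.stop + cutoff)
        ok = len(hits) > 0
        if ok:
            tp += 1
            captured.update((t.chrom, t.strand, int(h)) for h in hits)
        else:
            fp += 1
        termini[(t.chrom, t.strand, t.stop)] = ok
    tp_u = sum(1 for ok in termini.values() if ok)
    fp_u = len(termini) - tp_u
    return TerminusBenchmark(
        cutoff=cutoff,
        tp_transcripts=tp,
        fp_transcripts=fp,
        ppv=tp / (tp + fp) if tp + fp else 0.0,
        unique_true_sites_captured=len(captured),
        tp_unique_termini=tp_u,
        fp_unique_termini=fp_u,
        ppv_unique_termini=tp_u / len(termini) if termini else 0.0,
    )
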