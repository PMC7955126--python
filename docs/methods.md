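# Methods

This note records the model, its assumptions, the defaults that matter,
and the design choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem and model

Transcript assemblies built from RNA-Seq misannotate 3′ termini: read
coverage past a cleavage site (precursor mRNA, incomplete termination)
drags assembled ends downstream, and lowly used alternative
polyadenylation (APA) isoforms are dropped. `apafind` treats 3′-end
refinement as supervised sequence labelling over genomic bins: every
100-base bin of a transcript's (extended, coverage-refined) terminal
exon is classified "contains an expressed polyA site" or not, using
features from both DNA sequence and read coverage, and positive bins are
folded back into the annotation as added isoforms. Labels for training
come from 3′-end sequencing (PolyA-Seq-style BED of cleavage positions).

Assumptions worth making explicit:

* polyA sites live in or downstream of the annotated 3′ terminal exon;
  internal exons and the intron chain are taken as given and never edited;
* the PAS hexamer sits ~10–35 nt upstream of the cleavage site on the
  transcript strand, with auxiliary elements positioned relative to it;
* coverage within a 3′ region is non-increasing in expectation along the
  direction of transcription, stepping down at each used site;
* truth labels are themselves imperfect (3′-seq has false positives and
  negatives); metrics are interpreted accordingly.

## Coordinates

Internal coordinates are 1-based inclusive throughout (GTF convention);
BED and bedGraph are converted at the I/O boundary only. "Upstream" and
"downstream" always refer to transcription order: feature windows on the
minus strand are reverse-complemented (sequence) and reversed (coverage)
before any feature logic runs, which makes feature extraction exactly
strand-symmetric (a property test asserts this).

## Transcript processing

1. **Isolate** the 3′ terminal exon of each transcript.
2. **Extend** its 3′ boundary by `10000 + 2*bin_size` bases (10,200 at
   the default bin size 100), clipped at the chromosome end and trimmed
   so the extension does not overlap the genomic span of any same-strand
   neighbour; never trimmed past the original stop.
3. **Refine**: walking 5′→3′ from the original stop in `bin_size`
   windows, truncate at the first window whose mean depth falls below
   `max(min_abs_cov, frac * D0)`, where `D0` is the mean depth over the
   window ending at the original stop. Defaults `min_abs_cov = 5`,
   `frac = 0.05`, both exposed in `pipeline.RefineParams`. This concrete
   rule is this package's instantiation of coverage-continuity
   refinement; the thresholds were chosen so that plausible read-through
   (a few percent of gene-body depth) survives while background noise
   does not. Refinement is idempotent and never shortens the region
   below the original terminal exon.
4. **Merge** overlapping refined regions (training only, so no genomic
   bin is duplicated across training sequences). Prediction keeps one
   region per transcript.
5. **Bin**: tile the region with `bin_size`-wide bins from its 5′
   boundary; a trailing remnant shorter than one bin is dropped so all
   real bins have identical width. A bin is labelled 1 iff ≥1 truth site
   falls inside it on the same strand. Sequences are padded at the 3′
   tail to `max_len = 300` bins (30,000 bases); regions longer than that
   are split into consecutive 300-bin chunks rather than truncated, so
   no genomic span is silently unexaminable. Padding side (3′) was an
   open choice; tail padding keeps bin index 0 = region 5′ end.

## Features (27 per bin)

Each real bin is featurized from a 300-base transcription-oriented
window: 100-nt upstream flank, the bin, 100-nt downstream flank. Flanks
beyond chromosome ends are filled with `N` / depth 0.

**PAS (4, values ±1).** A 6-base sliding window scans window offsets
[65, 200) — from 35 nt upstream of the bin's 5′ edge to the bin's 3′
edge, which is where a PAS must sit for a site anywhere in the bin — for
(1) `AATAAA`, (2) `ATTAAA`, (3) `AGTAAA`, (4) any of the eight minor
variants `AAGAAA, AAAAAG, AATACA, TATAAA, GATAAA, AATATA, CATAAA,
AATAGA`. The best match (priority canonical > ATTAAA > AGTAAA > minor,
ties 3′-most) anchors the element windows.

**Sequence elements (8, values ±1).** With anchor P (PAS offset, or the
bin 5′ edge + 15 as a neutral anchor when no PAS is present): downstream
D = [P+6, P+106), upstream U = [P−100, P), near-downstream
N = [P+6, P+40), clipped to the window. Indicators: ≥3 non-overlapping
`GGG` in D; ≥2 `TTT` in N; ≥6 overlapping `GT`/`TG` dimers in D; ≥2
`GTGT`/`TGTG` in D; T fraction ≥ 0.4 over the first 30 bases of D; T
fraction ≥ 0.4 over the last 30 bases of U; ≥2 `TGTA`/`TATA` in U; A+T
fraction ≥ 0.65 over U∪D. All regions and thresholds sit in
`FeatureConfig` and are hashed into the model bundle, so a trained model
refuses inputs featurized under a different configuration. These
concrete definitions encode the literature's positional grammar
(GU-rich/U-rich downstream elements, UGUA upstream); the exact numbers
are package defaults, not claims.

**Coverage contrasts (14, real).** Median depth damps spikes. Intra-bin:
medians m_U, m_M, m_D of the window's three 100-base thirds. Inter-bin:
medians M_U, M_M, M_D of the previous / current / next real bin along
the region (missing neighbours — region ends and chunk boundaries — are
zeros). For each triple (u, m, d), seven bounded contrasts:
`s(u,m), s(m,d), s(u,d)` with `s(a,b) = (a−b)/(a+b+1)`; `log1p(m)`;
`log1p(u)−log1p(m)`; `log1p(m)−log1p(d)`; `d/(u+1)`. The `s` form keeps
every feature finite at zero coverage and |s| < 1. At the default bin
size the intra and inter triples coincide for interior bins and differ
at region edges; both are kept for robustness at other bin sizes.

**Annotation end (1, ±1).** 1 iff any source transcript's original stop
lies in the bin.

Feature order is frozen (`features.FEATURE_NAMES`) and versioned via the
config hash.

## Classifier

One bidirectional LSTM layer, 20 units per direction (40 total), over
the 300×27 sequence, followed by a dense sigmoid head per bin. Padded
timesteps are masked in the recurrence itself (state carries through
unchanged), in the loss, in standardization statistics and in all
metrics; a test verifies that corrupting padded slots changes nothing.

Training: region-level 60/20/20 split (chunks of one region never
straddle partitions); the 14 coverage features z-scored with
training-split statistics (zero-variance features centred only); class
weights `w_c = N/(2 N_c)` over real training bins to counter the heavy
class imbalance; binary cross-entropy; Adam, learning rate 0.01, batch
size 32, global-norm gradient clipping at 5; 25 epochs; the weights of
the minimum-validation-loss epoch are kept ("minimum loss" is read as
validation loss, since train loss decreases monotonically and the
monitoring exists to prevent overfitting). The learning rate is higher
than the common 10⁻³ default because the training sets here are small
and the epoch budget is fixed; it is exposed in `ModelConfig`. The
network is numpy throughout (`nn.py`) — forward, BPTT, Adam — with an
analytic-vs-numerical gradient check in the test suite; this removes any
dependence on a deep-learning runtime and makes training bit-reproducible
under a seed.

Flat per-bin baselines (random forest, logistic regression via
scikit-learn) share the prediction interface; tests use them as a sanity
floor for the sequence model.

Model bundles persist as `.npz` weights plus a JSON sidecar (feature
config hash, bin size, max length, standardization statistics, training
history); prediction refuses bundles whose bin size or feature hash
mismatch the inputs.

## Evaluation

Bin-level: P = Tp/(Tp+Fp), R = Tp/(Tp+Fn), F = 2PR/(P+R) at threshold
0.5 over real bins, with 0/0 → 0 so empty predictions score zero rather
than erroring. Average precision is the uninterpolated step sum
Σₙ (Rₙ−Rₙ₋₁)Pₙ over thresholds at each distinct predicted probability,
descending, R₀ = 0 — the right summary under heavy imbalance, where ROC
curves flatter. The implementation is cross-checked in tests against
both a brute-force threshold sweep and scikit-learn's
`average_precision_score` to 10⁻¹².

Transcriptome-level: a transcript terminus is a true positive iff a
truth site on the same chromosome and strand lies within ±100 bases
(inclusive — the boundary convention was open and is documented here).
Reported per transcript and per distinct terminus, plus the number of
distinct truth sites captured by at least one transcript.

## Integration

Every positive bin proposes a stop at its 3′-most base, suppressed when
(1) the input transcript's stop already lies in that bin, or (2) the
proposal is within 100 bases of that stop. Surviving proposals become
copies of the source transcript with only the terminal exon's 3′
boundary moved (ids `<source>.apa<k>`, k in genomic order); a proposal
that would invert the terminal exon (5′ of its original start) is
rejected and logged, since honouring it would require editing the intron
chain. Originals are always emitted unchanged. A proposal whose
resulting exon chain already exists in the input is skipped, which makes
integration idempotent across re-runs while still allowing distinct
isoforms to share a stop position (an optional `dedup_across_isoforms`
flag, default off, suppresses those too). Distinct isoforms of adjacent
positive bins each produce a transcript; downstream quantification is
expected to resolve their usage.

## Synthetic data

The generator (`apafind.synthetic`) emulates exactly the structure the
method assumes, at desk scale, with a manifest recording ground truth.
Defaults define the study conditions: 200 two-exon transcripts on both
strands of 2 chromosomes (9 kb anchor spacing, so extensions are
routinely trimmed against neighbours); 1–3 sites per transcript
(probabilities 0.3/0.4/0.3) at 400–900 nt into the terminal exon and
500–1,200 nt apart; PAS planted 10–35 nt upstream of each site
(canonical with probability 0.70, `ATTAAA` 0.15, `AGTAAA` 0.10, a minor
variant 0.05); GU-rich and U-rich downstream elements each planted with
probability 0.7; site usage decaying geometrically (factor 0.6,
normalized); depth 100× at the terminal-exon 5′ end, stepping down by
usage at each site over a 50-base linear ramp; a read-through tail of
10% of depth decaying over 600 bases; 5% depth over introns; per-base
Poisson noise. The annotated transcript stop is placed at the first
(most 5′) site ± ≤20 bases, so downstream sites are *absent from the
input annotation* — the situation the classifier is meant to repair, and
the basis of the site-recovery measurements.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: non-uniform background sequence
composition (real 3′ UTRs are AT-rich, so PAS-like hexamers occur far
more often by chance), mappability gaps and multi-mapping artifacts,
fragment-level coverage autocorrelation (noise here is independent per
base), overlapping genes and antisense transcription, and truth-label
noise. Real-data performance must be established on real labels; the
synthetic results establish correctness and the direction of effects
(e.g. that combining sequence and coverage channels beats either alone,
and that label shuffling collapses AP to prevalence).

`degrade()` provides controlled corruptions (strip all PAS hexamers from
both genome strands, zero the coverage, re-draw site positions) used to
isolate one information channel at a time.

## Numerical and scale choices

* Problem sizes: tests and the acceptance script train on fixtures of
  24–200 transcripts (≈350–3,400 real bins); one training run of the
  25-epoch biLSTM on the 200-transcript fixture takes well under a
  minute on one CPU.
* Degenerate inputs: regions shorter than one bin are skipped with a
  warning; all-one-class training labels raise; average precision with
  no positive labels raises; 0/0 metric conventions are 0.
* Tie-breaks: PAS class priority then 3′-most occurrence; merge is
  strand-specific and merges only genuine overlaps (adjacency is not
  overlap).
* Reproducibility: every stochastic component (generator, split,
  weight init, batch order) draws from `numpy.random.default_rng`
  seeded from explicit config fields.

## Known limitations

* The refinement rule and element-region definitions are declared
  defaults, not fitted quantities; other datasets may want different
  `RefineParams`/`FeatureConfig`.
* Chunk boundaries of >300-bin regions lose their inter-bin neighbour
  context (treated as missing).
* BAM coverage is unstranded; stranded analyses should supply per-strand
  bedGraphs (e.g. from `bedtools genomecov -strand`).
* No pre-trained weights are distributed; users train on their own
  3′-seq labels or the synthetic fixture.
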