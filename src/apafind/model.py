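"""Training and applying the bin-sequence classifier.

The classifier is a bidirectional LSTM (20 units per direction) over each
region's 300-bin feature sequence with a per-bin sigmoid head. Training
uses a region-level 60/20/20 split, z-scoring of the 14 coverage features
on training-set statistics, inverse-frequency class weights, binary
cross-entropy with Adam for 25 epochs, and keeps the weights of the
minimum-validation-loss epoch. Flat per-bin baselines (random forest,
logistic regression) share the prediction interface for comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .core import BinSequence
from .features import N_FEATURES, RNA_SLICE, FeatureConfig
from .nn import Adam, BiLSTM, masked_bce

logger = logging.getLogger(__name__)

DNA_INDICES = tuple(range(0, 12))
RNA_INDICES = tuple(range(12, 26))


@dataclass
class ModelConfig:
    hidden_units_per_direction: int = 20
    epochs: int = 25
    threshold: float = 0.5
    split_fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0
    bin_size: int = 100
    max_len: int = 300
    class_weighting: Literal["inverse_frequency", "none"] = "inverse_frequency"
    learning_rate: float = 0.01
    batch_size: int = 32
    feature_subset: Literal["all", "dna", "rna"] = "all"

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class Standardization:
    """Per-feature mean/sd for the 14 coverage features, from training data."""

    mean: np.ndarray
    sd: np.ndarray

    def to_json(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_json(cls, d: dict) -> "Standardization":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]))


@dataclass
class TrainedModel:
    kind: Literal["bilstm", "random_forest", "linear"]
    weights: dict | object
    standardization: Standardization
    feature_config_hash: str
    bin_size: int
    max_len: int
    config: ModelConfig
    history: list[dict] = field(default_factory=list)

    @property
    def best_val_loss(self) -> float:
        return min(h["val_loss"] for h in self.history) if self.history else np.nan


@dataclass
class Predictions:
    """Per-bin probabilities and thresholded calls; padded bins carry none."""

    probs: np.ndarray  # (n_seq, max_len)
    mask: np.ndarray   # (n_seq, max_len) bool
    threshold: float

    @property
    def calls(self) -> np.ndarray:
        return ((self.probs >= self.threshold) & self.mask).astype(np.int8)

    def flat(self, labels: np.ndarray | None = None):
        m = self.mask.ravel()
        out = [self.probs.ravel()[m], self.calls.ravel()[m]]
        if labels is not None:
            out.append(labels.ravel()[m])
        return out


def stack_sequences(
    sequences: Sequence[BinSequence],
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """(X, y, mask) arrays of shape (n, max_len, F) / (n, max_len)."""
    X = np.stack([bs.X for bs in sequences])
    mask = np.stack([bs.mask for bs in sequences])
    y = None
    if all(bs.labels is not None for bs in sequences):
        y = np.stack([bs.labels for bs in sequences]).astype(float)
    return X, y, mask


def split_data(
    sequences: Sequence[BinSequence],
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20),
    seed: int = 0,
) -> tuple[list[BinSequence], list[BinSequence], list[BinSequence]]:
    """Region-level train/validation/test split, reproducible under seed.

    Chunks of the same region always land in the same partition so no
    genomic span leaks between sets.
    """
    groups: dict[int, list[BinSequence]] = {}
    order: list[int] = []
    for bs in sequences:
        key = id(bs.region)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(bs)
    if len(order) < 3:
        raise ValueError("need at least 3 regions to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(order))
    n_train = int(np.floor(fractions[0] * len(order)))
    n_val = int(np.floor(fractions[1] * len(order)))
    n_train = max(n_train, 1)
    n_val = max(n_val, 1)
    parts: list[list[BinSequence]] = [[], [], []]
    for rank, gi in enumerate(perm):
        which = 0 if rank < n_train else (1 if rank < n_train + n_val else 2)
        parts[which].extend(groups[order[gi]])
    if not parts[2]:
        raise ValueError("test split is empty; provide more regions")
    return parts[0], parts[1], parts[2]


def standardize(
    sequences: Sequence[BinSequence],
    stats: Standardization | None = None,
) -> tuple[list[BinSequence], Standardization]:
    """Z-score the 14 coverage features; binary features untouched.

    Statistics come from the real bins of the given sequences when
    ``stats`` is None (training set), otherwise the provided training-set
    statistics are applied. Zero-variance features are centred only.
    """
    if stats is None:
        rows = np.concatenate(
            [bs.X[bs.mask][:, RNA_SLICE] for bs in sequences], axis=0
        )
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0)
        stats = Standardization(mean=mean, sd=sd)
    sd_safe = np.where(stats.sd == 0, 1.0, stats.sd)
    out = []
    for bs in sequences:
        X = bs.X.copy()
        X[bs.mask, RNA_SLICE] = (X[bs.mask, RNA_SLICE] - stats.mean) / sd_safe
        out.append(
            BinSequence(
                region=bs.region, bin_size=bs.bin_size, max_len=bs.max_len,
                starts=bs.starts, ends=bs.ends, mask=bs.mask,
                labels=bs.labels, X=X, chunk_index=bs.chunk_index,
            )
        )
    return out, stats


def _subset_matrix(X: np.ndarray, subset: str) -> np.ndarray:
    """Zero out the feature channels outside the requested subset.

    'dna' keeps the 12 sequence indicators, 'rna' the 14 coverage
    features; the annotation-end feature belongs to neither single-omics
    view.
    """
    if subset == "all":
        return X
    X = X.copy()
    keep = DNA_INDICES if subset == "dna" else RNA_INDICES
    drop = [i for i in range(N_FEATURES) if i not in keep]
    X[..., drop] = 0.0
    return X


def class_weights(y: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency weights w_c = N / (2 * N_c) over real bins."""
    yy = y[mask.astype(bool)]
    n = len(yy)
    n1 = float(yy.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("training labels are all one class")
    return n / (2.0 * n0), n / (2.0 * n1)


def _precision_recall(probs, y, mask, threshold):
    calls = (probs >= threshold) & mask.astype(bool)
    pos = (y > 0.5) & mask.astype(bool)
    tp = float((calls & pos).sum())
    fp = float((calls & ~pos).sum())
    fn = float((~calls & pos).sum())
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def train(
    train_seqs: Sequence[BinSequence],
    val_seqs: Sequence[BinSequence],
    config: ModelConfig,
    standardization: Standardization | None = None,
    feature_config: FeatureConfig | None = None,
) -> TrainedModel:
    """Fit the biLSTM; returns the weights of the minimum-val-loss epoch.

    Expects sequences already standardized (pass the training-set stats so
    they are stored in the bundle for prediction time).
    """
    Xtr, ytr, mtr = stack_sequences(train_seqs)
    Xva, yva, mva = stack_sequences(val_seqs)
    if ytr is None or yva is None:
        raise ValueError("training requires labeled sequences")
    Xtr = _subset_matrix(Xtr, config.feature_subset)
    Xva = _subset_matrix(Xva, config.feature_subset)
    if config.class_weighting == "inverse_frequency":
        cw = class_weights(ytr, mtr)
    else:
        if ytr[mtr].sum() in (0, len(ytr[mtr])):
            raise ValueError("training labels are all one class")
        cw = (1.0, 1.0)

    net = BiLSTM(
        Xtr.shape[2], hidden=config.hidden_units_per_direction, seed=config.seed
    )
    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(Xtr)
    history: list[dict] = []
    best = (np.inf, net.copy_params())
    for epoch in range(config.epochs):
        for idx in np.array_split(
            rng.permutation(n), max(1, int(np.ceil(n / config.batch_size)))
        ):
            probs, cache = net.forward(Xtr[idx], mtr[idx], return_cache=True)
            _, dlogit = masked_bce(probs, ytr[idx], mtr[idx], cw)
            grads = net.backward(cache, dlogit)
            opt.step(net.params, grads)
        ptr = net.forward(Xtr, mtr)
        pva = net.forward(Xva, mva)
        loss, _ = masked_bce(ptr, ytr, mtr, cw)
        val_loss, _ = masked_bce(pva, yva, mva, cw)
        trP, trR = _precision_recall(ptr, ytr, mtr, config.threshold)
        vaP, vaR = _precision_recall(pva, yva, mva, config.threshold)
        history.append(
            {
                "epoch": epoch + 1, "loss": loss, "val_loss": val_loss,
                "precision": trP, "recall": trR,
                "val_precision": vaP, "val_recall": vaR,
            }
        )
        logger.info(
            "epoch %d loss %.4f val_loss %.4f val P %.3f R %.3f",
            epoch + 1, loss, val_loss, vaP, vaR,
        )
        if val_loss < best[0]:
            best = (val_loss, net.copy_params())
    fc = feature_config or FeatureConfig()
    return TrainedModel(
        kind="bilstm",
        weights=best[1],
        standardization=standardization
        or Standardization(np.zeros(14), np.ones(14)),
        feature_config_hash=fc.hash(),
        bin_size=config.bin_size,
        max_len=config.max_len,
        config=config,
        history=history,
    )


def train_alternative_head(
    train_seqs: Sequence[BinSequence],
    val_seqs: Sequence[BinSequence],
    kind: Literal["random_forest", "linear"],
    config: ModelConfig,
    standardization: Standardization | None = None,
    feature_config: FeatureConfig | None = None,
) -> TrainedModel:
    """Flat per-bin baseline (sequence context dropped) with the same API."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression

    Xtr, ytr, mtr = stack_sequences(train_seqs)
    Xtr = _subset_matrix(Xtr, config.feature_subset)
    rows = Xtr[mtr.astype(bool)]
    labs = ytr[mtr.astype(bool)]
    if labs.sum() in (0, len(labs)):
        raise ValueError("training labels are all one class")
    if kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=200, class_weight="balanced_subsample",
            random_state=config.seed, n_jobs=1,
        )
    elif kind == "linear":
        est = LogisticRegression(
            max_iter=2000, class_weight="balanced", random_state=config.seed
        )
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.fit(rows, labs)
    fc = feature_config or FeatureConfig()
    return TrainedModel(
        kind=kind,
        weights=est,
        standardization=standardization
        or Standardization(np.zeros(14), np.ones(14)),
        feature_config_hash=fc.hash(),
        bin_size=config.bin_size,
        max_len=config.max_len,
        config=config,
    )


def predict(
    model: TrainedModel,
    sequences: Sequence[BinSequence],
    threshold: float | None = None,
    prestandardized: bool = False,
) -> Predictions:
    """Per-bin probabilities for featurized sequences.

    Applies the model's stored standardization unless the sequences were
    standardized already. Refuses inputs with a mismatched feature
    configuration or bin size.
    """
    if sequences and sequences[0].bin_size != model.bin_size:
        raise ValueError(
            f"model was trained at bin_size {model.bin_size}, "
            f"got {sequences[0].bin_size}"
        )
    if not prestandardized:
        sequences, _ = standardize(sequences, model.standardization)
    X, _, mask = stack_sequences(sequences)
    X = _subset_matrix(X, model.config.feature_subset)
    thr = model.config.threshold if threshold is None else threshold
    if model.kind == "bilstm":
        net = BiLSTM(
            X.shape[2], hidden=model.config.hidden_units_per_direction
        )
        net.set_params(model.weights)
        probs = net.forward(X, mask.astype(float))
    else:
        flat = X[mask.astype(bool)]
        p = model.weights.predict_proba(flat)[:, 1]
        probs = np.zeros(mask.shape)
        probs[mask.astype(bool)] = p
    probs = probs * mask  # padded bins carry no prediction
    return Predictions(probs=probs, mask=mask.astype(bool), threshold=thr)


def check_feature_config(model: TrainedModel, feature_config: FeatureConfig) -> None:
    if model.feature_config_hash != feature_config.hash():
        raise ValueError(
            "feature configuration mismatch: the model was trained with a "
            "different feature config than the one supplied"
        )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a biLSTM bundle: weights (.npz) + JSON sidecar (.json)."""
    if model.kind != "bilstm":
        raise NotImplementedError("only biLSTM bundles are persisted")
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.weights)
    meta = {
        "kind": model.kind,
        "standardization": model.standardization.to_json(),
        "feature_config_hash": model.feature_config_hash,
        "bin_size": model.bin_size,
        "max_len": model.max_len,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.config).items()
        },
        "history": model.history,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["split_fractions"] = tuple(cfg["split_fractions"])
    config = ModelConfig(**cfg)
    with np.load(path.with_suffix(".npz")) as npz:
        weights = {k: npz[k] for k in npz.files}
    return TrainedModel(
        kind=meta["kind"],
        weights=weights,
        standardization=Standardization.from_json(meta["standardization"]),
        feature_config_hash=meta["feature_config_hash"],
        bin_size=meta["bin_size"],
        max_len=meta["max_len"],
        config=config,
        history=meta["history"],
    )
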