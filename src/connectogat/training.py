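"""Splitting, training, cross-validation, metrics, and permutation testing.

The classifier is trained with Adam on the mean cross-entropy over the
training graphs, with early stopping on validation loss. Evaluation
follows the conventions of the study design this package implements:
10% held-out test set, remaining data split 80/20 into train/validation,
10-fold stratified cross-validation reported as the mean of fold
validation accuracies, and label-permutation testing of the observed
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import NodeFeatureMatrix, minmax_normalize
from .gat import ForwardResult, GATConfig, GATModel

POSITIVE_LABEL = 1  # patients are the positive class


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.10
    val_fraction_of_remainder: float = 0.20
    folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.val_fraction_of_remainder):
            if not 0 < f < 1:
                raise ValueError(f"fractions must be in (0,1), got {f}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 5e-3
    weight_decay: float = 5e-4
    batch_size: int = 32
    early_stopping_patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid training configuration")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class GraphSample:
    """One model-ready graph: normalized features, binary adjacency, label."""

    features: np.ndarray  # n x F
    adjacency: np.ndarray  # n x n binary (no self-loops required)
    label: int
    subject_id: str = ""
    origin: str = "real"


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(y_true, y_pred) -> Metrics:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    accuracy = (tp + tn) / y_true.size
    return Metrics(accuracy, precision, recall, f1, np.array([[tn, fp], [fn, tp]]))


def split_dataset(
    items: list, labels: np.ndarray | None = None, spec: SplitSpec = SplitSpec()
) -> tuple[list, list, list]:
    """Deterministic stratified (train, val, test) partition of any item list.

    Defaults carve out 10% test, then 20% of the remainder as validation
    (a 150-sample cohort yields 108/27/15).
    """
    labels = np.asarray(
        labels if labels is not None else [it.label for it in items], dtype=int
    )
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class to stratify")
    idx = np.arange(len(items))
    strat = labels if spec.stratified else None
    rest, test = train_test_split(
        idx,
        test_size=spec.test_fraction,
        random_state=spec.seed,
        stratify=strat,
    )
    strat_rest = labels[rest] if spec.stratified else None
    train, val = train_test_split(
        rest,
        test_size=spec.val_fraction_of_remainder,
        random_state=spec.seed,
        stratify=strat_rest,
    )
    pick = lambda ii: [items[i] for i in sorted(ii)]
    return pick(train), pick(val), pick(test)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _epoch_pass(
    model: GATModel,
    samples: list[GraphSample],
    training: bool,
    rng: np.random.Generator | None,
) -> tuple[float, float, list[int]]:
    """One pass over samples; returns (mean loss, accuracy, predictions).
    In training mode gradients are accumulated (caller steps/zeroes)."""
    total, correct, preds = 0.0, 0, []
    inv_n = 1.0 / len(samples)
    for s in samples:
        out = model.forward(
            s.features, s.adjacency, training=training, rng=rng
        )
        nll = -out.log_probs.take_rows([s.label]).sum()
        if training:
            (nll * inv_n).backward()
        total += float(nll.data)
        preds.append(out.predicted)
        correct += int(out.predicted == s.label)
    return total * inv_n, correct * inv_n, preds


def evaluate(model: GATModel, samples: list[GraphSample]) -> Metrics:
    _, _, preds = _epoch_pass(model, samples, training=False, rng=None)
    return compute_metrics([s.label for s in samples], preds)


def train_model(
    train: list[GraphSample],
    val: list[GraphSample],
    model_cfg: GATConfig,
    train_cfg: TrainConfig,
) -> tuple[GATModel, TrainHistory]:
    """Train with Adam + early stopping on validation loss; the parameters
    of the best validation epoch are restored before returning."""
    model = GATModel(replace(model_cfg, seed=train_cfg.seed))
    if train_cfg.epochs == 0:
        return model, TrainHistory()
    rng = np.random.default_rng(train_cfg.seed + 1)
    opt = Adam(model.params, train_cfg.learning_rate, train_cfg.weight_decay)
    hist = TrainHistory()
    best_val = np.inf
    best_params: dict[str, np.ndarray] = {}
    patience_left = train_cfg.early_stopping_patience
    order = np.arange(len(train))
    for epoch in range(train_cfg.epochs):
        # minibatch passes: one Adam step per shuffled batch
        rng.shuffle(order)
        losses, correct = [], 0
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [train[i] for i in order[start : start + train_cfg.batch_size]]
            model.zero_grad()
            b_loss, b_acc, _ = _epoch_pass(model, batch, training=True, rng=rng)
            opt.step()
            losses.append(b_loss * len(batch))
            correct += int(round(b_acc * len(batch)))
        tr_loss = float(np.sum(losses) / len(train))
        tr_acc = correct / len(train)
        if not np.isfinite(tr_loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss = {tr_loss}"
            )
        va_loss, va_acc, _ = (
            _epoch_pass(model, val, training=False, rng=None)
            if val
            else (tr_loss, tr_acc, [])
        )
        hist.train_loss.append(tr_loss)
        hist.train_accuracy.append(tr_acc)
        hist.val_loss.append(va_loss)
        hist.val_accuracy.append(va_acc)
        if va_loss < best_val - 1e-9:
            best_val = va_loss
            hist.best_epoch = epoch
            best_params = {k: t.data.copy() for k, t in model.params.items()}
            patience_left = train_cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_params:
        for k, t in model.params.items():
            t.data = best_params[k]
    return model, hist


# ---------------------------------------------------------------------------
# cross-validation and permutation testing
# ---------------------------------------------------------------------------

def normalize_samples(
    train_feats: list[NodeFeatureMatrix],
    other_feats: list[NodeFeatureMatrix],
):
    tr, ot, scaler = minmax_normalize(train_feats, other_feats)
    return tr, ot, scaler


@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    mean_accuracy: float
    sd_accuracy: float
    mean_f1: float

    def to_dict(self) -> dict:
        return {
            "folds": [m.to_dict() for m in self.fold_metrics],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_f1": self.mean_f1,
        }


def cross_validate(
    samples: list[GraphSample],
    feats: list[NodeFeatureMatrix],
    model_cfg: GATConfig,
    train_cfg: TrainConfig,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV; the min-max scaler is refit inside each fold.

    ``feats`` are the raw (unnormalized) feature matrices aligned with
    ``samples``. The summary accuracy is the mean of the fold validation
    accuracies.
    """
    labels = np.array([s.label for s in samples])
    if folds > min(np.bincount(labels, minlength=2)):
        raise ValueError("folds exceed minority class count")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        tr_norm, va_norm, _ = normalize_samples(
            [feats[i] for i in tr_idx], [feats[i] for i in va_idx]
        )
        tr = [
            replace_features(samples[i], f.values)
            for i, f in zip(tr_idx, tr_norm)
        ]
        va = [
            replace_features(samples[i], f.values)
            for i, f in zip(va_idx, va_norm)
        ]
        model, _ = train_model(
            tr, va, model_cfg, replace(train_cfg, seed=train_cfg.seed + fold)
        )
        fold_metrics.append(evaluate(model, va))
    accs = np.array([m.accuracy for m in fold_metrics])
    f1s = np.array([m.f1 for m in fold_metrics])
    return CVResult(fold_metrics, float(accs.mean()), float(accs.std()), float(f1s.mean()))


def replace_features(sample: GraphSample, values: np.ndarray) -> GraphSample:
    return GraphSample(
        np.asarray(values, dtype=float),
        sample.adjacency,
        sample.label,
        sample.subject_id,
        sample.origin,
    )


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    mode: str


def permutation_test(
    samples: list[GraphSample],
    feats: list[NodeFeatureMatrix],
    model_cfg: GATConfig,
    train_cfg: TrainConfig,
    spec: SplitSpec = SplitSpec(),
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "retrain",
) -> PermutationResult:
    """Label-permutation significance test of validation accuracy.

    ``mode='retrain'`` re-runs the full train/evaluate pipeline per
    permutation (faithful but expensive). ``mode='cheap'`` trains once and
    permutes only the evaluation labels — an approximation for smoke-level
    calibration. p uses the add-one estimator (1 + #{null >= obs}) / (1 + P).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(samples))
    tr_i, va_i, _ = split_dataset(list(idx), np.array([s.label for s in samples]), spec)

    def run(labels: np.ndarray) -> float:
        tr_norm, va_norm, _ = normalize_samples(
            [feats[i] for i in tr_i], [feats[i] for i in va_i]
        )
        tr = [
            GraphSample(f.values, samples[i].adjacency, int(labels[i]))
            for i, f in zip(tr_i, tr_norm)
        ]
        va = [
            GraphSample(f.values, samples[i].adjacency, int(labels[i]))
            for i, f in zip(va_i, va_norm)
        ]
        model, _ = train_model(tr, va, model_cfg, train_cfg)
        return evaluate(model, va).accuracy

    true_labels = np.array([s.label for s in samples])
    observed = run(true_labels)
    null = np.empty(n_permutations)
    if mode == "retrain":
        for p in range(n_permutations):
            null[p] = run(rng.permutation(true_labels))
    elif mode == "cheap":
        tr_norm, va_norm, _ = normalize_samples(
            [feats[i] for i in tr_i], [feats[i] for i in va_i]
        )
        tr = [
            GraphSample(f.values, samples[i].adjacency, int(true_labels[i]))
            for i, f in zip(tr_i, tr_norm)
        ]
        va = [
            GraphSample(f.values, samples[i].adjacency, int(true_labels[i]))
            for i, f in zip(va_i, va_norm)
        ]
        model, _ = train_model(tr, va, model_cfg, train_cfg)
        _, _, preds = _epoch_pass(model, va, training=False, rng=None)
        preds = np.array(preds)
        va_labels = true_labels[np.array(va_i)]
        observed = float((preds == va_labels).mean())
        for p in range(n_permutations):
            null[p] = float((preds == rng.permutation(va_labels)).mean())
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    p_value = (1.0 + float((null >= observed - 1e-12).sum())) / (1.0 + n_permutations)
    return PermutationResult(observed, null, p_value, mode)
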