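"""Training and evaluation: regression pretraining, transfer fine-tuning,
scratch baselines, stratified k-fold splits and repeated 90/10 evaluation.

Optimization uses a decoupled-weight-decay Adam (the stated weight decay of
0.01 presumes a decoupled scheme); regression uses mean squared error and
classification binary cross-entropy on the logit.  Early stopping monitors
validation loss with the configured patience and restores the
best-validation weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import gat_net
from .autodiff import Tensor
from .gat_net import ModelConfig, ModelState
from .mol_graph import MoleculeGraph, featurize

__all__ = [
    "TrainConfig",
    "EvalReport",
    "pretrain",
    "finetune",
    "train_scratch",
    "stratified_kfold",
    "repeated_split_eval",
    "metric_rmse",
    "metric_roc_auc",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4  # fine-tuning default is 5e-5; see finetune()
    weight_decay: float = 0.01
    patience: int = 10
    max_epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    validation_fraction: float = 0.1
    freeze_bn_stats: bool = False  # train with stored normalization statistics

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


FINETUNE_LEARNING_RATE = 5e-5


@dataclass
class EvalReport:
    metric: str
    per_split: list[float]
    seeds: dict[str, int] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_split))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_split, ddof=1)) if len(self.per_split) > 1 else 0.0


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metric_rmse(predictions, targets) -> float:
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must have equal length")
    return float(np.sqrt(np.mean((predictions - targets) ** 2)))


def metric_roc_auc(scores, labels) -> float:
    """ROC-AUC as the Mann-Whitney rank statistic with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined with a single class")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay (decay skips biases and norm params)."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for name, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            m_hat = self.m[name] / (1 - self.b1 ** self.t)
            v_hat = self.v[name] / (1 - self.b2 ** self.t)
            update = m_hat / (np.sqrt(v_hat) + self.eps)
            # decay weight matrices only, never biases or norm parameters
            if self.weight_decay and p.data.ndim >= 2:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# shared fit loop
# ---------------------------------------------------------------------------

def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    # stable composition: softplus(x) - t*x, softplus via relu + log1p(exp(-|x|))
    abs_neg = -(logits * np.sign(logits.data))
    softplus = logits.relu() + (abs_neg.exp() + 1.0).log()
    return (softplus - logits * targets).mean()


def _loss(state: ModelState, graphs, targets: np.ndarray, training: bool,
          rng: np.random.Generator | None,
          bn_training: bool | None = None) -> Tensor:
    preds, _ = gat_net._forward_batch(state, graphs, training=training,
                                      dropout_rng=rng, bn_training=bn_training)
    if state.config.head_kind == "regression":
        diff = preds - targets
        return (diff * diff).mean()
    return _bce_with_logits(preds, targets)


def _eval_loss(state: ModelState, graphs, targets: np.ndarray,
               batch_size: int) -> float:
    total, count = 0.0, 0
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start:start + batch_size]
        t = targets[start:start + batch_size]
        loss = _loss(state, chunk, t, training=False, rng=None)
        total += float(loss.data) * len(chunk)
        count += len(chunk)
    return total / count


def _fit(state: ModelState, train_graphs, train_targets, val_graphs, val_targets,
         config: TrainConfig, learning_rate: float) -> list[dict]:
    rng = np.random.default_rng(config.seed)
    optimizer = AdamW(state.params, lr=learning_rate,
                      weight_decay=config.weight_decay)
    history: list[dict] = []
    best_val = np.inf
    best_params = None
    best_stats = None
    stale = 0
    n = len(train_graphs)
    train_targets = np.asarray(train_targets, dtype=float)
    val_targets = np.asarray(val_targets, dtype=float)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_graphs[i] for i in idx]
            loss = _loss(state, batch, train_targets[idx], training=True, rng=rng,
                         bn_training=not config.freeze_bn_stats)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {float(loss.data)}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        val_loss = _eval_loss(state, val_graphs, val_targets, config.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: v.data.copy() for k, v in state.params.items()}
            best_stats = {k: v.copy() for k, v in state.bn_stats.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_params is not None:
        for k, v in best_params.items():
            state.params[k].data = v
        state.bn_stats = best_stats
    return history


def _featurize_records(records) -> tuple[list[MoleculeGraph], np.ndarray]:
    graphs = [featurize(s) for s, _ in records]
    targets = np.asarray([t for _, t in records], dtype=float)
    return graphs, targets


def _split_validation(n: int, fraction: float, rng: np.random.Generator,
                      labels: np.ndarray | None = None):
    """Random (optionally stratified) validation split of range(n)."""
    n_val = max(1, int(round(n * fraction)))
    if labels is None:
        perm = rng.permutation(n)
        return perm[n_val:], perm[:n_val]
    val_idx: list[int] = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        cls_idx = rng.permutation(cls_idx)
        n_cls = max(1, int(round(len(cls_idx) * fraction)))
        val_idx.extend(cls_idx[:n_cls])
    val = np.asarray(sorted(val_idx))
    train = np.asarray(sorted(set(range(n)) - set(val_idx)))
    return train, val


# ---------------------------------------------------------------------------
# public training API
# ---------------------------------------------------------------------------

def pretrain(config: TrainConfig, dataset, model_config: ModelConfig | None = None,
             return_history: bool = False, standardize_targets: bool = True):
    """Train a regression model from scratch on ``(smiles, value)`` records.

    With ``standardize_targets`` the model learns z-scored targets; the
    mean/sd are stored on the returned state (``target_mean``/``target_sd``)
    and :func:`predict_values` maps raw output back to original units.
    Training-history losses are in standardized units.
    """
    config.validate()
    if len(dataset) < 2:
        raise ValueError("pretraining requires at least 2 records")
    graphs, targets = _featurize_records(dataset)
    if not np.all(np.isfinite(targets)):
        raise ValueError("pretraining targets must be finite")
    if np.ptp(targets) == 0:
        warnings.warn("all pretraining targets identical; model will be constant")
    if model_config is None:
        model_config = ModelConfig(head_kind="regression")
    if model_config.head_kind != "regression":
        raise ValueError("pretraining requires a regression head")
    state = gat_net.init_model(model_config, seed=config.seed)
    if standardize_targets:
        state.target_mean = float(targets.mean())
        state.target_sd = float(max(targets.std(), 1e-8))
        targets = (targets - state.target_mean) / state.target_sd
    rng = np.random.default_rng(config.seed + 1)
    train_idx, val_idx = _split_validation(len(graphs), config.validation_fraction, rng)
    history = _fit(
        state,
        [graphs[i] for i in train_idx], targets[train_idx],
        [graphs[i] for i in val_idx], targets[val_idx],
        config, config.learning_rate,
    )
    return (state, history) if return_history else state


def predict_values(state: ModelState, graphs) -> np.ndarray:
    """Regression predictions in original target units."""
    if state.config.head_kind != "regression":
        raise ValueError("predict_values requires a regression head")
    raw = gat_net.predict_batch(state, graphs)
    return state.target_mean + state.target_sd * raw


def finetune(pretrained: ModelState, dataset, config: TrainConfig,
             head_kind: str = "binary-classification",
             learning_rate: float | None = None,
             return_history: bool = False):
    """Transfer the pretrained backbone to classification.

    The two fully connected head layers are replaced by newly initialized
    ones; all layers then train at the (smaller) fine-tune learning rate.
    """
    config.validate()
    if head_kind != "binary-classification":
        raise ValueError(
            "fine-tuning replaces the head with a classifier; "
            "head_kind must be 'binary-classification'"
        )
    if pretrained.config.head_kind != "regression":
        raise ValueError("expected a pretrained regression checkpoint")
    if learning_rate is None:
        learning_rate = FINETUNE_LEARNING_RATE
    graphs, targets = _featurize_records(dataset)
    if not set(np.unique(targets)) <= {0.0, 1.0}:
        raise ValueError("fine-tuning labels must be binary 0/1")

    state = pretrained.copy()
    state.config.head_kind = "binary-classification"
    state.target_mean, state.target_sd = 0.0, 1.0  # logits, not values
    gat_net.reinit_head(state, seed=config.seed)

    rng = np.random.default_rng(config.seed + 1)
    train_idx, val_idx = _split_validation(
        len(graphs), config.validation_fraction, rng, labels=targets
    )
    history = _fit(
        state,
        [graphs[i] for i in train_idx], targets[train_idx],
        [graphs[i] for i in val_idx], targets[val_idx],
        config, learning_rate,
    )
    return (state, history) if return_history else state


def train_scratch(dataset, config: TrainConfig,
                  model_config: ModelConfig | None = None) -> ModelState:
    """Classification twin trained from random initialization (baseline)."""
    config.validate()
    if model_config is None:
        model_config = ModelConfig(head_kind="binary-classification")
    if model_config.head_kind != "binary-classification":
        raise ValueError("scratch baseline uses a binary-classification head")
    graphs, targets = _featurize_records(dataset)
    state = gat_net.init_model(model_config, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    train_idx, val_idx = _split_validation(
        len(graphs), config.validation_fraction, rng, labels=targets
    )
    _fit(
        state,
        [graphs[i] for i in train_idx], targets[train_idx],
        [graphs[i] for i in val_idx], targets[val_idx],
        config, config.learning_rate,
    )
    return state


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` folds, stratified by label.

    Within each class, shuffled indices are dealt round-robin so per-fold
    class counts differ by at most one.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("stratified folds require both classes present")
    smallest = min(int((labels == c).sum()) for c in classes)
    if k < 2 or k > smallest:
        raise ValueError(
            f"k={k} must be in [2, smallest class count = {smallest}]"
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    position = 0  # continues across classes so folds stay equally sized
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for sample in idx:
            folds[sample] = position % k
            position += 1
    return folds


def _stratified_split(labels: np.ndarray, test_fraction: float,
                      rng: np.random.Generator):
    test_idx: list[int] = []
    for cls in np.unique(labels):
        cls_idx = rng.permutation(np.flatnonzero(labels == cls))
        n_test = max(1, int(round(len(cls_idx) * test_fraction)))
        test_idx.extend(cls_idx[:n_test])
    test = np.asarray(sorted(test_idx))
    train = np.asarray(sorted(set(range(len(labels))) - set(test_idx)))
    return train, test


def repeated_split_eval(model_builder, dataset, n_splits: int = 10,
                        test_fraction: float = 0.1, seed: int = 0,
                        max_retries: int = 20) -> EvalReport:
    """Repeated stratified train/test splits scored by held-out ROC-AUC.

    ``model_builder(train_records, seed)`` must return an object scoring
    molecules: either a ModelState with a classification head, or anything
    with a ``predict_records(records) -> scores`` method.
    """
    labels = np.asarray([t for _, t in dataset], dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    for split in range(n_splits):
        for attempt in range(max_retries):
            train_idx, test_idx = _stratified_split(labels, test_fraction, rng)
            if len(np.unique(labels[test_idx])) == 2:
                break
            warnings.warn("single-class test split; resampling")
        else:
            raise RuntimeError("could not draw a two-class test split")
        train_records = [dataset[i] for i in train_idx]
        test_records = [dataset[i] for i in test_idx]
        model = model_builder(train_records, seed + split)
        if hasattr(model, "predict_records"):
            scores = np.asarray(model.predict_records(test_records), dtype=float)
        else:
            graphs = [featurize(s) for s, _ in test_records]
            scores = gat_net.predict_batch(model, graphs)
        aucs.append(metric_roc_auc(scores, labels[test_idx]))
    if n_splits == 1:
        warnings.warn("single split: standard deviation reported as 0")
    return EvalReport(metric="roc_auc", per_split=aucs,
                      seeds={"split_seed": seed})
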