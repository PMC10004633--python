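"""Training, evaluation and cross-validation for the graph classifier.

Training follows the published protocol: one graph per step (batch size 1),
cross-entropy loss, Adam updates, dropout 0.5 after the dense readout layer,
and a 9:1 train/test split inside 10-fold cross-validation.  All randomness
(weight init, epoch-level shuffling, dropout) derives from a single seed, so
identical inputs reproduce identical histories bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .graph_io import GraphDataset, GraphInputError, stratified_kfold
from .model import (ModelConfig, _model_backward, _model_forward_cache,
                    init_params, make_model_config, resolve_sortpool_k)

logger = logging.getLogger("dgcnn2")

__all__ = [
    "TrainConfig",
    "EvalReport",
    "CVReport",
    "TrainingDivergedError",
    "train_model",
    "evaluate",
    "cross_validate",
    "DATASET_PRESETS",
    "preset_config",
]

#: Published per-dataset settings: stage-1 16th-layer output channels and epochs.
DATASET_PRESETS = {
    "MUTAG": {"stage1_out_channels": 32, "epochs": 300},
    "PTC": {"stage1_out_channels": 64, "epochs": 200},
    "NCI1": {"stage1_out_channels": 128, "epochs": 200},
    "PROTEINS": {"stage1_out_channels": 32, "epochs": 100},
    "DD": {"stage1_out_channels": 128, "epochs": 200},
}


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimisation."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 1
    seed: int = 0
    optimizer: str = "adam"
    shuffle: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise GraphInputError("epochs must be positive")
        if self.learning_rate < 0:
            raise GraphInputError("learning_rate must be nonnegative")
        if self.batch_size != 1:
            raise GraphInputError("only batch size 1 is supported")
        if self.optimizer != "adam":
            raise GraphInputError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class EvalReport:
    accuracy: float
    cross_entropy: float
    auc: Optional[float]
    n: int


@dataclass
class CVReport:
    fold_reports: list
    mean_accuracy: float
    std_accuracy: float

    @property
    def fold_accuracies(self):
        return [r.accuracy for r in self.fold_reports]


def preset_config(name: str, n_classes: int = 2, **overrides) -> tuple:
    """(ModelConfig, TrainConfig) for a named benchmark dataset preset."""
    if name not in DATASET_PRESETS:
        raise GraphInputError(
            f"unknown preset {name!r}; choose from {sorted(DATASET_PRESETS)}"
        )
    p = DATASET_PRESETS[name]
    model = make_model_config(n_classes=n_classes,
                              stage1_out_channels=p["stage1_out_channels"])
    train = TrainConfig(epochs=overrides.pop("epochs", p["epochs"]), **overrides)
    return model, train


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def train_model(train_set: GraphDataset, model_config: ModelConfig,
                train_config: TrainConfig,
                eval_set: Optional[GraphDataset] = None):
    """Train fresh parameters; returns (params, resolved config, history).

    ``history`` is a list of per-epoch dicts with mean loss and train accuracy
    (plus test accuracy/AUC when ``eval_set`` is given).
    """
    if len(train_set) == 0:
        raise GraphInputError("empty training set")
    config = resolve_sortpool_k(model_config,
                                [g.node_count for g in train_set.graphs])
    rng = np.random.default_rng(train_config.seed)
    params = init_params(config, train_set.alphabet_size, rng)
    opt = _Adam(params, train_config.learning_rate)
    history = []
    order = np.arange(len(train_set))
    for epoch in range(train_config.epochs):
        if train_config.shuffle:
            rng.shuffle(order)
        losses = []
        correct = 0
        for gi in order:
            graph = train_set.graphs[gi]
            probs, cache = _model_forward_cache(graph, config, params,
                                                train_mode=True,
                                                dropout_rng=rng)
            y = graph.class_label
            loss = -np.log(max(probs[y], 1e-300))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}, graph {gi}"
                )
            losses.append(loss)
            correct += int(np.argmax(probs) == y)
            dlogits = probs.copy()
            dlogits[y] -= 1.0
            grads = _model_backward(dlogits, cache, config, params)
            opt.step(params, grads)
        record = {"epoch": epoch + 1, "loss": float(np.mean(losses)),
                  "train_acc": correct / len(train_set)}
        if eval_set is not None:
            rep = evaluate(params, eval_set, config)
            record["test_acc"] = rep.accuracy
            record["test_auc"] = rep.auc
        history.append(record)
        logger.debug("epoch %d: loss %.4f acc %.3f", epoch + 1,
                     record["loss"], record["train_acc"])
    return params, config, history


def evaluate(params: dict, dataset: GraphDataset,
             config: ModelConfig) -> EvalReport:
    """Accuracy (argmax, lowest index on ties), mean cross-entropy, and — for
    binary tasks with both classes present — the rank-statistic AUC."""
    if len(dataset) == 0:
        raise GraphInputError("empty dataset")
    y_true, scores = [], []
    correct = 0
    ce = 0.0
    for graph in dataset.graphs:
        probs, _ = _model_forward_cache(graph, config, params)
        pred = int(np.argmax(probs))  # argmax takes the lowest index on ties
        correct += int(pred == graph.class_label)
        ce += -np.log(max(probs[graph.class_label], 1e-300))
        y_true.append(graph.class_label)
        scores.append(probs[1] if config.n_classes == 2 else np.nan)
    auc = None
    if config.n_classes == 2 and len(set(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return EvalReport(accuracy=correct / len(dataset),
                      cross_entropy=ce / len(dataset), auc=auc, n=len(dataset))


def cross_validate(dataset: GraphDataset, model_config: ModelConfig,
                   train_config: TrainConfig, n_folds: int = 10,
                   stratified: bool = True, repeats: int = 1) -> CVReport:
    """k-fold cross-validation with fresh parameters per fold.

    Fold assignment and per-fold training seeds all derive from
    ``train_config.seed``, so a rerun reproduces the identical report.
    """
    fold_reports = []
    for rep in range(repeats):
        folds = stratified_kfold(dataset, n_folds,
                                 seed=train_config.seed + rep,
                                 stratified=stratified)
        for fi, (train_idx, test_idx) in enumerate(folds):
            fold_seed = train_config.seed + 10007 * (rep * n_folds + fi + 1)
            cfg = replace(train_config, seed=fold_seed)
            try:
                params, resolved, _ = train_model(dataset.subset(train_idx),
                                                  model_config, cfg)
                report = evaluate(params, dataset.subset(test_idx), resolved)
            except Exception as exc:
                raise type(exc)(f"fold {fi + 1}: {exc}") from exc
            fold_reports.append(report)
            logger.info("fold %d/%d: accuracy %.3f", fi + 1, n_folds,
                        report.accuracy)
    accs = np.array([r.accuracy for r in fold_reports])
    return CVReport(fold_reports=fold_reports, mean_accuracy=float(accs.mean()),
                    std_accuracy=float(accs.std()))
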