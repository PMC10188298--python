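"""Property prediction: predictor head, BCE/RMSE losses, ROC-AUC, fine-tuning.

The predictor is three fully connected ReLU layers (default widths
4096/512/64, scaled down for small model dims) feeding a linear task-output
layer of width T. Classification trains with masked binary cross-entropy on
sigmoid outputs; regression trains with mean squared error on targets
standardized over the observed training labels (predictions are mapped back
to the original scale for all reported metrics). Missing labels are excluded
from every loss and metric via the observed mask.

Fine-tuning updates the whole network (encoder included) unless the encoder
is frozen in the config; the epoch with the best validation metric is kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .autograd import Adam, Tensor
from .model import CLAPSModel
from .smiles_data import PropertyDataset, SplitAssignment

logger = logging.getLogger(__name__)

__all__ = ["bce_loss", "rmse", "roc_auc", "PredictorHead", "finetune",
           "predict", "EvaluationReport", "PropertyModel", "FinetuneResult"]


# ---------------------------------------------------------------------------
# Losses and metrics
# ---------------------------------------------------------------------------

def bce_loss(o: np.ndarray, t: np.ndarray, observed: np.ndarray | None = None) -> float:
    """Masked binary cross-entropy, averaged over observed entries."""
    o, t = np.asarray(o, float), np.asarray(t, float)
    observed = np.ones_like(o, bool) if observed is None else np.asarray(observed, bool)
    if o.shape != t.shape or o.shape != observed.shape:
        raise ValueError("shape mismatch")
    if not observed.any():
        raise ValueError("no observed entries")
    oo, tt = o[observed], t[observed]
    eps = 1e-12
    return float(-np.mean(tt * np.log(oo + eps) + (1 - tt) * np.log(1 - oo + eps)))


def rmse(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """Root mean squared error."""
    Y, Y_hat = np.asarray(Y, float).ravel(), np.asarray(Y_hat, float).ravel()
    if Y.shape != Y_hat.shape:
        raise ValueError("length mismatch")
    if Y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((Y - Y_hat) ** 2)))


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            observed: np.ndarray | None = None) -> float:
    """ROC-AUC with ties counted 1/2; multi-task inputs are evaluated per
    task over observed entries and macro-averaged. Single-class tasks are
    skipped with a warning; if every task is single-class this is an error."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, float)
    if scores.ndim == 1:
        scores, labels = scores[:, None], labels[:, None]
        observed = None if observed is None else np.asarray(observed, bool)[:, None]
    observed = (np.ones_like(scores, bool) if observed is None
                else np.asarray(observed, bool))
    per_task: list[float] = []
    for t in range(scores.shape[1]):
        m = observed[:, t]
        y, s = labels[m, t], scores[m, t]
        if y.size == 0 or len(np.unique(y)) < 2:
            logger.warning("task %d has a single class; skipped in ROC-AUC", t)
            continue
        per_task.append(float(roc_auc_score(y, s)))
    if not per_task:
        raise ValueError("no task with both classes present")
    return float(np.mean(per_task))


@dataclass
class EvaluationReport:
    task_type: str
    per_task: dict[str, float]
    macro: float
    metric: str                       # "roc_auc" | "rmse"

    def to_dict(self) -> dict:
        return {"task_type": self.task_type, "metric": self.metric,
                "macro": self.macro, "per_task": self.per_task}


# ---------------------------------------------------------------------------
# Predictor head
# ---------------------------------------------------------------------------

class PredictorHead:
    """Three FC ReLU layers plus a linear task-output layer of width T."""

    def __init__(self, d_in: int, n_tasks: int,
                 dims: tuple[int, ...] = (4096, 512, 64), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dims = tuple(dims)
        widths = [d_in, *dims, n_tasks]
        self.W: list[Tensor] = []
        self.b: list[Tensor] = []
        for a, b in zip(widths[:-1], widths[1:]):
            self.W.append(Tensor(rng.normal(0, 1 / math.sqrt(a), (a, b)),
                                 requires_grad=True))
            self.b.append(Tensor(np.zeros(b), requires_grad=True))

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.b]

    def forward(self, h: Tensor) -> Tensor:
        x = h
        for W, b in zip(self.W[:-1], self.b[:-1]):
            x = (x @ W + b).relu()
        return x @ self.W[-1] + self.b[-1]   # logits / raw values


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class PropertyModel:
    """A fine-tuned encoder + predictor head bound to one task layout."""

    base: CLAPSModel
    head: PredictorHead
    task_type: str
    task_names: list[str]
    y_mean: np.ndarray = field(default_factory=lambda: np.zeros(1))
    y_std: np.ndarray = field(default_factory=lambda: np.ones(1))

    def parameters(self) -> list[Tensor]:
        params = list(self.head.parameters())
        if not self.base.config.freeze_encoder:
            params = self.base.parameters()[:1] + self.base.encoder.parameters() + params
        return params

    def forward_scores(self, mols, rng=None) -> Tensor:
        h = self.base.forward_representations(mols, rng=rng)
        return self.head.forward(h)

    def scores(self, mols) -> np.ndarray:
        """Evaluation-mode outputs: probabilities for classification, values
        on the original target scale for regression."""
        out = self.forward_scores(mols).data
        if self.task_type == "classification":
            return 1.0 / (1.0 + np.exp(-out))
        return out * self.y_std + self.y_mean


@dataclass
class FinetuneResult:
    model: PropertyModel
    report: EvaluationReport
    history: list[dict]


def _masked_bce_graph(logits: Tensor, targets: np.ndarray,
                      observed: np.ndarray) -> Tensor:
    m = observed.astype(np.float64)
    t = np.where(observed, targets, 0.0)
    o = logits.sigmoid()
    eps = 1e-12
    ll = Tensor(t) * (o + eps).log() + Tensor(1.0 - t) * (1.0 - o + eps).log()
    return -(ll * Tensor(m)).sum() * (1.0 / m.sum())


def _masked_mse_graph(pred: Tensor, targets: np.ndarray,
                      observed: np.ndarray) -> Tensor:
    m = observed.astype(np.float64)
    t = np.where(observed, targets, 0.0)
    diff = (pred - Tensor(t)) * Tensor(m)
    return (diff * diff).sum() * (1.0 / m.sum())


def _evaluate(pm: PropertyModel, mols, labels, observed,
              batch: int = 256) -> EvaluationReport:
    outs = np.vstack([pm.scores(mols[i:i + batch])
                      for i in range(0, len(mols), batch)])
    if pm.task_type == "classification":
        per = {}
        for t, name in enumerate(pm.task_names):
            m = observed[:, t]
            if m.sum() and len(np.unique(labels[m, t])) == 2:
                per[name] = float(roc_auc_score(labels[m, t], outs[m, t]))
        macro = roc_auc(outs, labels, observed)
        return EvaluationReport("classification", per, macro, "roc_auc")
    per = {}
    for t, name in enumerate(pm.task_names):
        m = observed[:, t]
        if m.sum():
            per[name] = rmse(labels[m, t], outs[m, t])
    macro = float(np.mean(list(per.values())))
    return EvaluationReport("regression", per, macro, "rmse")


def finetune(ds: PropertyDataset, split: SplitAssignment, model: CLAPSModel,
             config=None, seed: int = 0) -> FinetuneResult:
    """Fine-tune a (pre)trained encoder on a property dataset.

    Trains on the train subset, selects the epoch with the best validation
    metric (macro ROC-AUC up / RMSE down), and reports metrics on the test
    subset. The projection head from pretraining is discarded; a fresh
    predictor head is attached to the pooled representation.
    """
    config = config if config is not None else model.config
    rng = np.random.default_rng(seed)
    try:
        mols = [model.encode_smiles(s) for s in ds.smiles]
    except KeyError as exc:
        raise ValueError(f"vocabulary mismatch between checkpoint and dataset: {exc}")

    head = PredictorHead(config.d, ds.n_tasks, dims=config.predictor_dims,
                         seed=seed + 17)
    pm = PropertyModel(base=model, head=head, task_type=ds.task_type,
                       task_names=ds.task_names or
                       [f"task{t}" for t in range(ds.n_tasks)])
    train_idx = np.asarray(split.train, int)
    y = ds.labels.copy()
    if ds.task_type == "regression":
        obs_train = ds.observed[train_idx]
        vals = np.where(obs_train, y[train_idx], np.nan)
        pm.y_mean = np.nanmean(vals, axis=0)
        pm.y_std = np.nanstd(vals, axis=0)
        pm.y_std[pm.y_std == 0] = 1.0
        y = (y - pm.y_mean) / pm.y_std

    opt = Adam(pm.parameters(), lr=config.lr_finetune,
               weight_decay=config.weight_decay)
    val_mols = [mols[i] for i in split.valid]
    test_mols = [mols[i] for i in split.test]
    best_metric, best_state, best_epoch = None, None, -1
    last_decay_epoch = -1
    beta = config.weight_ema
    ema_state = None  # Polyak average of weights; evaluated instead of the
    #                   raw iterate when enabled (smoother, generalizes better)
    history: list[dict] = []
    higher_better = ds.task_type == "classification"
    bs = min(config.batch_size, 64)

    for epoch in range(config.epochs_finetune):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(train_idx), bs):
            rows = train_idx[order[start:start + bs]]
            chunk = [mols[i] for i in rows]
            out = pm.forward_scores(chunk, rng=rng)
            if ds.task_type == "classification":
                loss = _masked_bce_graph(out, ds.labels[rows], ds.observed[rows])
            else:
                loss = _masked_mse_graph(out, y[rows], ds.observed[rows])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        if beta > 0.0:
            current = [p.data.copy() for p in pm.parameters()]
            if ema_state is None:
                ema_state = current
            else:
                ema_state = [beta * e + (1 - beta) * c
                             for e, c in zip(ema_state, current)]
            for p, e in zip(pm.parameters(), ema_state):
                np.copyto(p.data, e)
        val = _evaluate(pm, val_mols, ds.labels[split.valid],
                        ds.observed[split.valid])
        if beta > 0.0:
            for p, c in zip(pm.parameters(), current):
                np.copyto(p.data, c)
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                        "val_metric": val.macro})
        better = (best_metric is None or
                  (val.macro > best_metric if higher_better else val.macro < best_metric))
        if better:
            best_metric, best_epoch = val.macro, epoch
            best_state = ([e.copy() for e in ema_state] if beta > 0.0
                          else [p.data.copy() for p in pm.parameters()])
        elif epoch - best_epoch >= config.patience:
            break
        elif (epoch - max(best_epoch, last_decay_epoch)
              >= max(2, config.patience // 3)):
            # halve the step size when validation stalls (reduce-on-plateau)
            opt.lr = max(opt.lr * 0.5, config.lr_finetune * 1e-2)
            last_decay_epoch = epoch
    if best_state is not None:
        for p, saved in zip(pm.parameters(), best_state):
            np.copyto(p.data, saved)
    report = _evaluate(pm, test_mols, ds.labels[split.test],
                       ds.observed[split.test])
    return FinetuneResult(model=pm, report=report, history=history)


def predict(pm: PropertyModel, smiles_list: list[str]) -> tuple[np.ndarray, list[str | None]]:
    """Per-molecule, per-task outputs. Unparsable or over-length SMILES get a
    NaN row and an error message; the run continues."""
    n_tasks = len(pm.task_names)
    out = np.full((len(smiles_list), n_tasks), np.nan)
    errors: list[str | None] = [None] * len(smiles_list)
    good, rows = [], []
    for i, s in enumerate(smiles_list):
        try:
            good.append(pm.base.encode_smiles(s))
            rows.append(i)
        except (ValueError, KeyError) as exc:
            errors[i] = str(exc)
    for start in range(0, len(good), 256):
        chunk = good[start:start + 256]
        out[rows[start:start + 256]] = pm.scores(chunk)
    return out, errors
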