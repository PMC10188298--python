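"""Desk-scale benchmark protocols on synthetic corpora.

These fix the exact conditions under which the pipeline is exercised
end-to-end on a single CPU: corpus sizes, planted-label noise, the reduced
model configuration, and the fine-tuning recipe per task. Tests and the
reproduction script both call these functions, so the conditions cannot
drift apart.

Protocols (fixed once; see the methods note for rationale):

* pretraining sanity — 200 molecules, 5 epochs, d = 32, batch 64.
* classification recovery — 600 molecules, "contains sulfur" labels with 5%
  flips, scaffold split, desk defaults (mean pooling, dropout 0.2, lr 1e-3).
* regression recovery — 600 molecules, carbon-count labels with sigma = 0.1
  noise, scaffold split, sum pooling (the target is extensive), dropout 0,
  lr 3e-3, batch 16, up to 400 epochs with patience 120.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .contrastive import pretrain
from .model import CLAPSModel
from .predict import FinetuneResult, finetune
from .smiles_data import build_vocabulary, scaffold_split
from .synthetic import generate_synthetic_corpus, generate_synthetic_labels

__all__ = ["pretraining_sanity", "classification_recovery",
           "regression_recovery", "RecoveryRun"]


@dataclass
class RecoveryRun:
    test_metric: float          # macro ROC-AUC or RMSE on the test subset
    metric: str
    n_epochs: int
    pretrain_trace: list[float]


def _pretrained_model(corpus: list[str], config: RunConfig,
                      seed: int) -> tuple[CLAPSModel, list[float]]:
    model = CLAPSModel(build_vocabulary(corpus), config, seed=seed)
    trace = pretrain(corpus, model, config, seed=seed).loss_trace
    return model, trace


def pretraining_sanity(seed: int, n: int = 200, epochs: int = 5) -> list[float]:
    """Per-epoch mean contrastive loss on a small corpus (reduced dims)."""
    corpus = generate_synthetic_corpus(n, seed=seed)
    config = RunConfig.desk_scale(epochs_pretrain=epochs, seed=seed)
    return _pretrained_model(corpus, config, seed)[1]


def classification_recovery(seed: int, n: int = 600,
                            noise: float = 0.05) -> RecoveryRun:
    """Pretrain + fine-tune on the planted-motif classification task."""
    corpus = generate_synthetic_corpus(n, seed=seed)
    config = RunConfig.desk_scale(seed=seed)
    model, trace = _pretrained_model(corpus, config, seed)
    ds = generate_synthetic_labels(corpus, "classification", noise=noise,
                                   seed=seed)
    result = finetune(ds, scaffold_split(ds, seed=seed), model, config,
                      seed=seed)
    return RecoveryRun(test_metric=result.report.macro, metric="roc_auc",
                       n_epochs=len(result.history), pretrain_trace=trace)


def regression_recovery(seed: int, n: int = 600,
                        noise: float = 0.1) -> RecoveryRun:
    """Pretrain + fine-tune on the planted carbon-count regression task."""
    corpus = generate_synthetic_corpus(n, seed=seed)
    config = RunConfig.desk_scale(pooling="sum", dropout=0.0, lr_finetune=3e-3,
                                  batch_size=16, epochs_finetune=400,
                                  patience=120, seed=seed)
    model, trace = _pretrained_model(corpus, config, seed)
    ds = generate_synthetic_labels(corpus, "regression", noise=noise, seed=seed)
    result = finetune(ds, scaffold_split(ds, seed=seed), model, config,
                      seed=seed)
    return RecoveryRun(test_metric=result.report.macro, metric="rmse",
                       n_epochs=len(result.history), pretrain_trace=trace)
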