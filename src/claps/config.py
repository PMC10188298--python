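"""Run configuration: defaults, validation and YAML loading.

Full-scale defaults follow the published hyperparameter grid: roulette
masking at ratio 0.25, batch 1500, projection head (2048, 512), pretraining
learning rate 1e-3 and fine-tuning rate 1e-4, dropout 0.2, 30 pretraining
epochs, a 3-head PSS network, a 3-layer / 4-head encoder, and predictor
widths (4096, 512, 64). `desk_scale()` returns the reduced configuration
used throughout the test suite and worked examples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_STRATEGIES = ("roulette", "top", "random")


@dataclass
class RunConfig:
    strategy: str = "roulette"
    ratio: float = 0.25
    batch_size: int = 1500
    projection_hidden: int = 2048
    projection_out: int = 512
    lr_pretrain: float = 1e-3
    lr_finetune: float = 1e-4
    dropout: float = 0.2
    epochs_pretrain: int = 30
    pss_heads: int = 3
    pss_layers: int = 2
    encoder_layers: int = 3
    encoder_heads: int = 4
    temperature: float = 0.1
    max_len: int = 220            # fixed sequence length C
    d: int = 128                  # character embedding / model dimension
    predictor_dims: tuple[int, ...] = (4096, 512, 64)
    epochs_finetune: int = 100
    patience: int = 10
    pooling: str = "mean"
    weight_decay: float = 0.0           # decoupled L2, fine-tuning only
    weight_ema: float = 0.9             # Polyak averaging of fine-tune weights
                                        # per epoch; 0 disables
    roulette_probs: str = "attention"   # "attention" | "occurrence"
    freeze_encoder: bool = False
    seed: int = 0

    def __post_init__(self):
        self.predictor_dims = tuple(int(x) for x in self.predictor_dims)
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"strategy must be one of {_STRATEGIES}")
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("ratio must lie in (0, 1)")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (contrastive loss is "
                             "degenerate for a single pair)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.d % self.encoder_heads != 0:
            raise ValueError("d must be divisible by encoder_heads")
        if self.roulette_probs not in ("attention", "occurrence"):
            raise ValueError("roulette_probs must be 'attention' or 'occurrence'")
        if self.pooling not in ("mean", "sum"):
            raise ValueError("pooling must be 'mean' or 'sum'")
        for name in ("epochs_pretrain", "epochs_finetune", "patience",
                     "pss_heads", "pss_layers", "encoder_layers", "max_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        """Reduced configuration for CPU-scale corpora (hundreds of molecules)."""
        small = dict(batch_size=64, projection_hidden=64, projection_out=32,
                     epochs_pretrain=5, max_len=64, d=32,
                     predictor_dims=(128, 64, 32), epochs_finetune=60,
                     patience=10, lr_finetune=1e-3)
        small.update(overrides)
        return cls(**small)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["predictor_dims"] = list(self.predictor_dims)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        data.update(overrides)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
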