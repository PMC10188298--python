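"""Transformer encoder for SMILES strings and the contrastive projection head.

The encoder follows the post-norm transformer layer: four-head scaled
dot-product self-attention with per-head value projections and an output
projection, residual + LayerNorm, then a two-linear ReLU feed-forward with
residual + LayerNorm. Attention never attends to pad positions, and the
molecule representation h is pooled over non-pad positions only, so padding
content can never leak into h.

The projection head is the two-layer bias-free perceptron
z = W1 ReLU(W2 h) used only by the contrastive objective; it is discarded
when the encoder is reused for property prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, layer_norm, softmax

__all__ = ["EncoderConfig", "TransformerEncoder", "ProjectionHead",
           "encode_molecule", "project"]


@dataclass
class EncoderConfig:
    d: int = 128
    layers: int = 3
    heads: int = 4
    d_ff: int | None = None       # defaults to 4 * d
    dropout: float = 0.2
    pooling: str = "mean"         # "mean" | "sum" over non-pad positions

    def __post_init__(self):
        if self.d_ff is None:
            self.d_ff = 4 * self.d
        if self.d % self.heads != 0:
            raise ValueError("model dim d must be divisible by heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.pooling not in ("mean", "sum"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


def _param(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    scale = scale if scale is not None else 1.0 / math.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)


class TransformerEncoder:
    """Stack of post-norm transformer layers mapping (B, C, d) -> (B, C, d)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, dff = config.d, config.d_ff
        self.layers: list[dict[str, Tensor]] = []
        for _ in range(config.layers):
            self.layers.append({
                "Wq": _param(rng, d, d), "Wk": _param(rng, d, d),
                "Wv": _param(rng, d, d), "Wo": _param(rng, d, d),
                "ln1_g": Tensor(np.ones(d), requires_grad=True),
                "ln1_b": Tensor(np.zeros(d), requires_grad=True),
                "W1": _param(rng, d, dff), "b1": Tensor(np.zeros(dff), requires_grad=True),
                "W2": _param(rng, dff, d), "b2": Tensor(np.zeros(d), requires_grad=True),
                "ln2_g": Tensor(np.ones(d), requires_grad=True),
                "ln2_b": Tensor(np.zeros(d), requires_grad=True),
            })

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.values()]

    def _heads_view(self, t: Tensor, B: int, C: int) -> Tensor:
        h = self.config.heads
        return t.reshape(B, C, h, self.config.d // h).transpose(0, 2, 1, 3)

    def _dropout(self, t: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if rng is None or p == 0.0:
            return t
        keep = (rng.random(t.shape) >= p) / (1.0 - p)
        return t * Tensor(keep)

    def forward(self, X: Tensor, pad_mask: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        """Run the stack. `pad_mask` is (B, C) bool, True at real tokens.
        Pass `rng` to enable dropout (training mode)."""
        B, C, d = X.shape
        neg = np.where(pad_mask[:, None, None, :], 0.0, -1e9)  # (B,1,1,C) keys
        scale = 1.0 / math.sqrt(d // self.config.heads)
        for lp in self.layers:
            # scale folded into Q so the (B, h, C, C) score array is built once
            Q = self._heads_view(X @ lp["Wq"] * scale, B, C)
            K = self._heads_view(X @ lp["Wk"], B, C)
            V = self._heads_view(X @ lp["Wv"], B, C)
            att = softmax(Q @ K.swapaxes(-1, -2) + Tensor(neg), axis=-1)
            ctx = (att @ V).transpose(0, 2, 1, 3).reshape(B, C, d) @ lp["Wo"]
            X = layer_norm(X + self._dropout(ctx, rng), lp["ln1_g"], lp["ln1_b"])
            ff = ((X @ lp["W1"] + lp["b1"]).relu()) @ lp["W2"] + lp["b2"]
            X = layer_norm(X + self._dropout(ff, rng), lp["ln2_g"], lp["ln2_b"])
        return X

    def pool(self, X: Tensor, pad_mask: np.ndarray) -> Tensor:
        """Pool (B, C, d) to molecule representations h of shape (B, d)."""
        m = pad_mask.astype(np.float64)
        summed = (X * Tensor(m[:, :, None])).sum(axis=1)
        if self.config.pooling == "sum":
            return summed
        return summed * Tensor(1.0 / m.sum(axis=1)[:, None])


class ProjectionHead:
    """Bias-free two-layer perceptron z = W1 ReLU(W2 h)."""

    def __init__(self, d_in: int, hidden: int = 2048, d_out: int = 512,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W2 = _param(rng, d_in, hidden)
        self.W1 = _param(rng, hidden, d_out)

    def parameters(self) -> list[Tensor]:
        return [self.W2, self.W1]

    def forward(self, h: Tensor) -> Tensor:
        return (h @ self.W2).relu() @ self.W1


def project(head: ProjectionHead, h: np.ndarray) -> np.ndarray:
    """Evaluation-mode projection of one representation vector or a batch."""
    arr = np.atleast_2d(np.asarray(h, dtype=np.float64))
    z = head.forward(Tensor(arr)).data
    return z[0] if np.asarray(h).ndim == 1 else z


def encode_molecule(mol, model) -> np.ndarray:
    """Evaluation-mode representation h (length d) of one encoded molecule."""
    h = model.represent([mol])
    return h[0]
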