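"""Positive-sample selection: attention-guided character masking.

A small multilayer, multi-head self-attention network scores every character
of a SMILES string. Per head, Att_i = softmax(X W_q^i (X W_k^i)^T / sqrt(d))
over the non-pad positions; the per-character weight is the sum over heads of
the corresponding row sums, so the weight vector always totals heads * L.
A masking strategy then turns the weights into a set of positions whose
tokens are replaced by the mask token, yielding the positive sample.

Mask selection is discrete sampling, so no gradient flows from the
contrastive objective into this network; its parameters are fixed at their
seeded initialization unless updated externally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .smiles_data import EncodedMolecule, Vocabulary, tokenize

__all__ = [
    "PSSNetwork", "WeightVector", "MaskPlan", "attention_matrix",
    "weight_vector", "roulette_mask", "top_mask", "random_mask", "apply_mask",
    "occurrence_weights",
]


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class PSSNetwork:
    """Multilayer multi-head self-attention scorer.

    Each layer holds per-head query/key matrices of shape (d, d_k) with
    d_k = max(1, d // heads). Between layers the input is propagated as the
    head-averaged attention-weighted combination X <- mean_i Att_i X, so the
    attention of the last layer is computed on contextualized characters.
    """

    def __init__(self, d: int, heads: int = 3, layers: int = 2, seed: int = 0):
        if heads < 1 or layers < 1:
            raise ValueError("heads and layers must be >= 1")
        self.d, self.heads, self.layers = d, heads, layers
        d_k = max(1, d // heads)
        rng = np.random.default_rng(seed)
        scale = 1.0 / math.sqrt(d)
        self.W_q = [[rng.normal(0, scale, (d, d_k)) for _ in range(heads)]
                    for _ in range(layers)]
        self.W_k = [[rng.normal(0, scale, (d, d_k)) for _ in range(heads)]
                    for _ in range(layers)]

    def _layer_attention(self, X: np.ndarray, layer: int) -> np.ndarray:
        """Per-head L x L attention matrices for one layer; X is L x d."""
        atts = []
        for Wq, Wk in zip(self.W_q[layer], self.W_k[layer]):
            scores = (X @ Wq) @ (X @ Wk).T / math.sqrt(self.d)
            atts.append(_softmax_rows(scores))
        return np.stack(atts)

    def forward(self, X: np.ndarray, true_length: int) -> np.ndarray:
        """Last-layer per-head attention matrices over the non-pad prefix."""
        if true_length < 1:
            raise ValueError("true_length must be >= 1")
        Xl = np.asarray(X, dtype=np.float64)[:true_length]
        for layer in range(self.layers - 1):
            att = self._layer_attention(Xl, layer)
            Xl = att.mean(axis=0) @ Xl
        return self._layer_attention(Xl, self.layers - 1)


def attention_matrix(X: np.ndarray, net: PSSNetwork,
                     true_length: int) -> np.ndarray:
    """Per-head L x L row-stochastic attention matrices (L = true_length)."""
    return net.forward(X, true_length)


@dataclass
class WeightVector:
    """Per-character nonnegative masking weights for one molecule."""

    weights: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-D")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and nonnegative")

    def __len__(self) -> int:
        return self.weights.shape[0]


def weight_vector(att: np.ndarray, source: str = "") -> WeightVector:
    """w[r] = sum over heads and columns of Att_i[r, c]; totals heads * L."""
    att = np.asarray(att, dtype=np.float64)
    if att.ndim != 3 or att.shape[0] < 1:
        raise ValueError("expected a (heads, L, L) attention stack")
    return WeightVector(weights=att.sum(axis=(0, 2)), source=source)


def occurrence_weights(smiles: str) -> WeightVector:
    """Occurrence-frequency weights: w[i] = count of token i's type in the
    string. Alternative roulette weighting based on character frequency
    rather than attention."""
    tokens = tokenize(smiles)
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    return WeightVector(weights=np.array([counts[t] for t in tokens], float),
                        source=smiles)


@dataclass
class MaskPlan:
    """Positions chosen for masking under one strategy at one ratio."""

    positions: frozenset[int]
    ratio: float
    strategy: str
    true_length: int = 0

    def __post_init__(self):
        self.positions = frozenset(int(p) for p in self.positions)


def _n_masked(ratio: float, L: int) -> int:
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    return math.ceil(ratio * L)


def roulette_single_draw(weights: np.ndarray, rng: np.random.Generator) -> int:
    """One roulette-wheel draw: position i with probability w_i / sum(w).

    Implemented as the cumulative-sum rule: draw r in (0, 1]; select the
    first i with p_1 + ... + p_i >= r.
    """
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate weights: all zero")
    cum = np.cumsum(w / total)
    r = rng.random()
    return int(np.searchsorted(cum, r, side="left"))


def roulette_mask(w: WeightVector, ratio: float,
                  rng: np.random.Generator) -> MaskPlan:
    """Sequential roulette draws without replacement, each draw proportional
    to the remaining weights, until ceil(ratio * L) positions are chosen."""
    L = len(w)
    k = _n_masked(ratio, L)
    if w.weights.sum() <= 0:
        raise ValueError("degenerate weights: all zero")
    remaining = w.weights.copy()
    chosen: list[int] = []
    for _ in range(k):
        if remaining.sum() <= 0:
            # remaining mass exhausted: fall back to uniform over the rest
            pool = np.setdiff1d(np.arange(L), chosen)
            chosen.extend(rng.choice(pool, size=k - len(chosen),
                                     replace=False).tolist())
            break
        pos = roulette_single_draw(remaining, rng)
        chosen.append(pos)
        remaining[pos] = 0.0
    return MaskPlan(positions=frozenset(chosen), ratio=ratio,
                    strategy="roulette", true_length=L)


def top_mask(w: WeightVector, ratio: float) -> MaskPlan:
    """The ceil(ratio * L) largest-weight positions; ties at the cut go to
    the lower index. Deterministic."""
    L = len(w)
    k = _n_masked(ratio, L)
    order = np.lexsort((np.arange(L), -w.weights))  # weight desc, index asc
    return MaskPlan(positions=frozenset(order[:k].tolist()), ratio=ratio,
                    strategy="top", true_length=L)


def random_mask(true_length: int, ratio: float,
                rng: np.random.Generator) -> MaskPlan:
    """Uniform sample without replacement of ceil(ratio * L) positions."""
    k = _n_masked(ratio, true_length)
    pos = rng.choice(true_length, size=k, replace=False)
    return MaskPlan(positions=frozenset(pos.tolist()), ratio=ratio,
                    strategy="random", true_length=true_length)


def apply_mask(mol: EncodedMolecule, plan: MaskPlan,
               vocab: Vocabulary) -> EncodedMolecule:
    """Replace the planned positions with the mask id; pads untouched."""
    ids = mol.token_ids.copy()
    for p in plan.positions:
        if p >= mol.true_length:
            raise IndexError(f"mask position {p} >= true length {mol.true_length}")
        ids[p] = vocab.mask_id
    return EncodedMolecule(smiles=mol.smiles, token_ids=ids,
                           true_length=mol.true_length)
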