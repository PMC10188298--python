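"""Cosine similarity, NT-Xent contrastive loss, and the pretraining loop.

A minibatch of N molecules yields 2N projections, interleaved so rows
(2k, 2k+1) (0-based) are the k-th positive pair. The pair loss is

    l(i, j) = -log exp(Sim(z_i, z_j)/T) / sum_{k != i} exp(Sim(z_i, z_k)/T)

with the denominator running over all 2N - 1 rows other than i itself (the
partner j included), and the batch loss averages l over both orderings of
every pair. `nt_xent_batch` is the reference NumPy evaluation; the training
loop builds the identical quantity on the autodiff graph so gradients reach
the encoder, embeddings and projection head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Adam, Tensor

__all__ = ["ContrastiveBatch", "cosine_similarity", "nt_xent_pair",
           "nt_xent_batch", "pretrain", "PretrainResult"]


def cosine_similarity(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """Sim(z_i, z_j) = z_i . z_j / (||z_i|| ||z_j||), in [-1, 1]."""
    z_i, z_j = np.asarray(z_i, float), np.asarray(z_j, float)
    ni, nj = np.linalg.norm(z_i), np.linalg.norm(z_j)
    if ni == 0.0 or nj == 0.0:
        raise ValueError("zero-norm projection")
    return float(z_i @ z_j / (ni * nj))


@dataclass
class ContrastiveBatch:
    """2N projection rows; rows (2k, 2k+1) are the k-th positive pair."""

    projections: np.ndarray
    temperature: float

    def __post_init__(self):
        self.projections = np.asarray(self.projections, dtype=np.float64)
        if self.projections.ndim != 2 or self.projections.shape[0] % 2:
            raise ValueError("projections must be a (2N, d) matrix")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_pairs(self) -> int:
        return self.projections.shape[0] // 2

    def similarity_matrix(self) -> np.ndarray:
        z = self.projections
        norms = np.linalg.norm(z, axis=1)
        if np.any(norms == 0.0):
            raise ValueError("zero-norm projection")
        zn = z / norms[:, None]
        return zn @ zn.T


def nt_xent_pair(batch: ContrastiveBatch, i: int, j: int) -> float:
    """The pair loss l(i, j); indices are 0-based rows of the batch."""
    if i == j:
        raise ValueError("pair indices must differ")
    sim = batch.similarity_matrix() / batch.temperature
    logits = sim[i].copy()
    logits[i] = -np.inf  # exclude only k = i
    m = logits.max()
    log_denom = m + np.log(np.exp(logits - m).sum())
    return float(log_denom - sim[i, j])


def nt_xent_batch(batch: ContrastiveBatch) -> float:
    """L = (1/2N) sum_k [l(2k, 2k+1) + l(2k+1, 2k)] (0-based pairs)."""
    sim = batch.similarity_matrix() / batch.temperature
    n2 = sim.shape[0]
    np.fill_diagonal(sim, -np.inf)
    m = sim.max(axis=1, keepdims=True)
    log_denom = m[:, 0] + np.log(np.exp(sim - m).sum(axis=1))
    partner = np.arange(n2) ^ 1  # 2k <-> 2k+1
    pos = sim[np.arange(n2), partner]
    return float(np.mean(log_denom - pos))


def nt_xent_graph(z: Tensor, temperature: float) -> Tensor:
    """NT-Xent batch loss as an autodiff graph over projections z (2N, d)."""
    n2 = z.shape[0]
    norms = ((z * z).sum(axis=1, keepdims=True)) ** 0.5
    zn = z * norms**-1.0
    sim = zn @ zn.swapaxes(0, 1) * (1.0 / temperature)
    diag = Tensor(np.where(np.eye(n2, dtype=bool), -1e30, 0.0))
    masked = sim + diag
    shift = Tensor(masked.data.max(axis=1, keepdims=True))
    log_denom = (masked - shift).exp().sum(axis=1, keepdims=True).log() + shift
    partner = np.arange(n2) ^ 1
    onehot = Tensor(np.eye(n2)[partner])
    pos = (sim * onehot).sum(axis=1, keepdims=True)
    return (log_denom - pos).mean()


@dataclass
class PretrainResult:
    model: object
    loss_trace: list[float]      # per-epoch mean contrastive loss


def pretrain(corpus: list[str], model, config=None, seed: int = 0,
             progress=None) -> PretrainResult:
    """Contrastively pretrain `model` on a SMILES corpus.

    Every epoch reshuffles the corpus and redraws masks, so each molecule
    meets a fresh positive sample; each minibatch of N molecules contributes
    2N projections to the loss. The optimizer is Adam at the configured
    pretraining rate. Fully deterministic under `seed`.
    """
    config = config if config is not None else model.config
    if not corpus:
        raise ValueError("empty corpus")
    if config.batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    rng = np.random.default_rng(seed)
    mols = [model.encode_smiles(s) for s in corpus]
    opt = Adam(model.parameters(), lr=config.lr_pretrain)
    trace: list[float] = []
    for epoch in range(config.epochs_pretrain):
        order = rng.permutation(len(mols))
        losses: list[float] = []
        for start in range(0, len(mols), config.batch_size):
            chunk = [mols[i] for i in order[start:start + config.batch_size]]
            if len(chunk) < 2:
                continue
            interleaved: list = []
            for mol in chunk:
                interleaved.append(mol)
                interleaved.append(model.make_positive(mol, rng))
            h = model.forward_representations(interleaved, rng=rng)
            z = model.projection.forward(h)
            loss = nt_xent_graph(z, config.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
        if progress is not None:
            progress(epoch, trace[-1])
    return PretrainResult(model=model, loss_trace=trace)
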