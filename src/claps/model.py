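"""The full model: embeddings, positional encoding, encoder, projection, PSS.

`CLAPSModel` bundles everything the pretraining and prediction stages share:
the vocabulary, a trainable character-embedding table initialized N(0,1),
the constant sinusoidal positional matrix, the transformer encoder, the
contrastive projection head and the positive-sample-selection network.
Checkpoints are a directory holding the config (YAML), the vocabulary
(JSON) and all weights (NPZ).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .autograd import Tensor, embedding_rows
from .config import RunConfig
from .encoder import EncoderConfig, ProjectionHead, TransformerEncoder
from .pss import (MaskPlan, PSSNetwork, WeightVector, apply_mask,
                  occurrence_weights, random_mask, roulette_mask, top_mask,
                  weight_vector)
from .smiles_data import EncodedMolecule, Vocabulary, encode, positional_encoding

__all__ = ["CLAPSModel"]


class CLAPSModel:
    def __init__(self, vocab: Vocabulary, config: RunConfig, seed: int = 0):
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(seed)
        self.embedding = Tensor(rng.standard_normal((len(vocab), config.d)),
                                requires_grad=True)
        self.pe = positional_encoding(config.max_len, config.d)
        self.encoder = TransformerEncoder(
            EncoderConfig(d=config.d, layers=config.encoder_layers,
                          heads=config.encoder_heads, dropout=config.dropout,
                          pooling=config.pooling),
            seed=seed + 1)
        self.projection = ProjectionHead(config.d, config.projection_hidden,
                                         config.projection_out, seed=seed + 2)
        self.pss = PSSNetwork(config.d, heads=config.pss_heads,
                              layers=config.pss_layers, seed=seed + 3)

    # -- data plumbing --------------------------------------------------------

    def encode_smiles(self, smiles: str) -> EncodedMolecule:
        return encode(smiles, self.vocab, self.config.max_len)

    def batch_arrays(self, mols: list[EncodedMolecule]) -> tuple[np.ndarray, np.ndarray]:
        ids = np.stack([m.token_ids for m in mols])
        C = self.config.max_len
        mask = np.arange(C)[None, :] < np.array([m.true_length for m in mols])[:, None]
        return ids, mask

    # -- forward passes -------------------------------------------------------

    def forward_representations(self, mols: list[EncodedMolecule],
                                rng: np.random.Generator | None = None) -> Tensor:
        """Differentiable batch of representations h, shape (B, d).
        Pass `rng` to enable dropout (training mode).

        The batch is cropped to its longest molecule before the encoder runs:
        trailing pad columns are masked out of attention and pooling anyway,
        so the result is identical and the quadratic attention cost shrinks.
        """
        ids, mask = self.batch_arrays(mols)
        width = max(1, max(m.true_length for m in mols))
        ids, mask = ids[:, :width], mask[:, :width]
        X = embedding_rows(self.embedding, ids) + Tensor(self.pe[None, :width, :])
        X = self.encoder.forward(X, mask, rng=rng)
        return self.encoder.pool(X, mask)

    def represent(self, mols: list[EncodedMolecule]) -> np.ndarray:
        """Evaluation-mode representations (no dropout, no gradients)."""
        return self.forward_representations(mols, rng=None).data

    def represent_smiles(self, smiles_list: list[str]) -> np.ndarray:
        return self.represent([self.encode_smiles(s) for s in smiles_list])

    # -- positive-sample selection -------------------------------------------

    def pss_weights(self, mol: EncodedMolecule) -> WeightVector:
        """Attention-derived masking weights for one molecule."""
        X = self.embedding.data[mol.token_ids] + self.pe
        att = self.pss.forward(X, mol.true_length)
        return weight_vector(att, source=mol.smiles)

    def mask_plan(self, mol: EncodedMolecule,
                  rng: np.random.Generator) -> MaskPlan:
        cfg = self.config
        if cfg.strategy == "random":
            return random_mask(mol.true_length, cfg.ratio, rng)
        if cfg.strategy == "top":
            return top_mask(self.pss_weights(mol), cfg.ratio)
        if cfg.roulette_probs == "occurrence":
            return roulette_mask(occurrence_weights(mol.smiles), cfg.ratio, rng)
        return roulette_mask(self.pss_weights(mol), cfg.ratio, rng)

    def make_positive(self, mol: EncodedMolecule,
                      rng: np.random.Generator) -> EncodedMolecule:
        """One masked positive sample under the configured strategy."""
        return apply_mask(mol, self.mask_plan(mol, rng), self.vocab)

    # -- parameters and persistence ------------------------------------------

    def parameters(self) -> list[Tensor]:
        return [self.embedding, *self.encoder.parameters(),
                *self.projection.parameters()]

    def _weight_map(self) -> dict[str, np.ndarray]:
        out = {"embedding": self.embedding.data}
        for i, layer in enumerate(self.encoder.layers):
            for name, t in layer.items():
                out[f"enc{i}_{name}"] = t.data
        out["proj_W2"] = self.projection.W2.data
        out["proj_W1"] = self.projection.W1.data
        for l in range(self.pss.layers):
            for h in range(self.pss.heads):
                out[f"pss{l}_h{h}_Wq"] = self.pss.W_q[l][h]
                out[f"pss{l}_h{h}_Wk"] = self.pss.W_k[l][h]
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.config.save(directory / "config.yaml")
        self.vocab.save(directory / "vocab.json")
        np.savez(directory / "weights.npz", **self._weight_map())

    @classmethod
    def load(cls, directory: str | Path) -> "CLAPSModel":
        directory = Path(directory)
        config = RunConfig.from_yaml(directory / "config.yaml")
        vocab = Vocabulary.load(directory / "vocab.json")
        model = cls(vocab, config, seed=0)
        with np.load(directory / "weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        if weights["embedding"].shape[0] != len(vocab):
            raise ValueError("checkpoint vocabulary size does not match weights")
        for name, arr in model._weight_map().items():
            np.copyto(arr, weights[name])
        return model
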