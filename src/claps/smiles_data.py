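"""SMILES tokenization, vocabulary, fixed-length encoding and dataset handling.

The tokenizer is character-level with two exceptions: two-letter element
symbols (``Cl``, ``Br``) and bracket atoms (``[NH+]``, ``[C@H]``) are single
tokens, as are two-digit ring-closure labels (``%10``). Tokenization is
lossless — concatenating the tokens reproduces the input string exactly.

Molecules are encoded as fixed-length integer id sequences padded with a
dedicated pad token. Inputs longer than the fixed length ``C`` are a hard
error at this level (no silent truncation); corpus loaders drop and log them
instead.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

PAD_TOKEN = "<pad>"
MASK_TOKEN = "<mask>"

_TOKEN_RE = re.compile(r"\[[^\]]+\]|Br|Cl|%\d{2}|.")


def tokenize(s: str) -> list[str]:
    """Split a SMILES string into tokens; concatenation reproduces the input."""
    if not s:
        raise ValueError("cannot tokenize an empty string")
    tokens = _TOKEN_RE.findall(s)
    assert "".join(tokens) == s
    return tokens


@dataclass
class Vocabulary:
    """Bijective token <-> integer-id map with pad and mask specials.

    Tokens are kept in first-appearance order over the corpus; the pad and
    mask tokens are appended last, so ids are stable for a given corpus.
    """

    tokens: list[str]
    ids: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.ids = {t: i for i, t in enumerate(self.tokens)}
        if len(self.ids) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for t in self.tokens:
            if not t or any(c.isspace() for c in t):
                raise ValueError(f"invalid token {t!r}")
        if PAD_TOKEN not in self.ids or MASK_TOKEN not in self.ids:
            raise ValueError("vocabulary must contain pad and mask tokens")

    @property
    def pad_id(self) -> int:
        return self.ids[PAD_TOKEN]

    @property
    def mask_id(self) -> int:
        return self.ids[MASK_TOKEN]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.ids

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.tokens, indent=0) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text()))


def build_vocabulary(corpus) -> Vocabulary:
    """Collect every token type occurring in `corpus`, specials appended last."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    seen: dict[str, None] = {}
    for s in corpus:
        for t in tokenize(s):
            seen.setdefault(t)
    return Vocabulary(list(seen) + [PAD_TOKEN, MASK_TOKEN])


@dataclass
class EncodedMolecule:
    """A SMILES string as a fixed-length id sequence with its true length."""

    smiles: str
    token_ids: np.ndarray  # int64, length C
    true_length: int

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)


def encode(s: str, vocab: Vocabulary, C: int) -> EncodedMolecule:
    """Encode a SMILES string as ids, right-padded with the pad id to length C."""
    tokens = tokenize(s)
    if len(tokens) > C:
        raise ValueError(f"SMILES of {len(tokens)} tokens exceeds C={C}")
    ids = np.full(C, vocab.pad_id, dtype=np.int64)
    for i, t in enumerate(tokens):
        if t not in vocab:
            raise KeyError(f"unknown token {t!r}")
        ids[i] = vocab.ids[t]
    return EncodedMolecule(smiles=s, token_ids=ids, true_length=len(tokens))


def decode(mol: EncodedMolecule, vocab: Vocabulary) -> str:
    """Inverse of :func:`encode` for unmasked molecules."""
    return "".join(vocab.tokens[i] for i in mol.token_ids[: mol.true_length])


def positional_encoding(C: int, d: int) -> np.ndarray:
    """Sinusoidal positional matrix: PE[pos, 2i] = sin(pos / 10000^(2i/d)),
    PE[pos, 2i+1] = cos(pos / 10000^(2i/d))."""
    if d < 2 or d % 2 != 0:
        raise ValueError("d must be even and >= 2")
    pos = np.arange(C)[:, None]
    rate = 10000.0 ** (np.arange(0, d, 2) / d)
    pe = np.empty((C, d))
    pe[:, 0::2] = np.sin(pos / rate)
    pe[:, 1::2] = np.cos(pos / rate)
    return pe


class EmbeddingTable:
    """|vocab| x d character embeddings, initialized i.i.d. N(0,1)."""

    def __init__(self, vocab_size: int, d: int, seed: int = 0):
        self.d = d
        rng = np.random.default_rng(seed)
        self.matrix = rng.standard_normal((vocab_size, d))

    def __len__(self) -> int:
        return self.matrix.shape[0]


def embed(mol: EncodedMolecule, table: EmbeddingTable, pe: np.ndarray) -> np.ndarray:
    """X = S + P: token-embedding rows plus positional rows, shape C x d."""
    C = mol.token_ids.shape[0]
    if pe.shape != (C, table.matrix.shape[1]):
        raise ValueError(f"positional matrix shape {pe.shape} does not match "
                         f"(C={C}, d={table.matrix.shape[1]})")
    return table.matrix[mol.token_ids] + pe


# ---------------------------------------------------------------------------
# Property datasets
# ---------------------------------------------------------------------------

@dataclass
class PropertyDataset:
    """SMILES with an n x T label matrix and an observed mask.

    Classification labels are 0/1 where observed; unobserved cells hold NaN
    and are excluded from every loss and metric. `planted_rule` records the
    generating rule for synthetic data so recovery is checkable.
    """

    smiles: list[str]
    labels: np.ndarray          # n x T float
    observed: np.ndarray        # n x T bool
    task_type: str              # "classification" | "regression"
    task_names: list[str] = field(default_factory=list)
    planted_rule: str | None = None

    def __post_init__(self):
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=np.float64))
        self.observed = np.atleast_2d(np.asarray(self.observed, dtype=bool))
        if self.task_type not in ("classification", "regression"):
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if self.labels.shape != self.observed.shape:
            raise ValueError("labels and observed shapes differ")
        if len(self.smiles) != self.labels.shape[0]:
            raise ValueError("smiles and labels row counts differ")
        obs = self.labels[self.observed]
        if self.task_type == "classification":
            if not np.all(np.isin(obs, (0.0, 1.0))):
                raise ValueError("classification labels must be 0/1 where observed")
        elif not np.all(np.isfinite(obs)):
            raise ValueError("regression labels must be finite where observed")

    def __len__(self) -> int:
        return len(self.smiles)

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx) -> "PropertyDataset":
        idx = np.asarray(list(idx), dtype=int)
        return PropertyDataset(
            smiles=[self.smiles[i] for i in idx],
            labels=self.labels[idx],
            observed=self.observed[idx],
            task_type=self.task_type,
            task_names=self.task_names,
            planted_rule=self.planted_rule,
        )


def read_property_csv(path: str | Path, smiles_column: str,
                      label_columns: list[str], task_type: str) -> PropertyDataset:
    """Read a property CSV; blank cells become unobserved, bad SMILES dropped."""
    df = pd.read_csv(path)
    for col in [smiles_column, *label_columns]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    keep = df[smiles_column].map(
        lambda s: isinstance(s, str) and Chem.MolFromSmiles(s) is not None)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with unparsable SMILES from %s",
                       n_dropped, path)
    df = df[keep]
    labels = df[label_columns].to_numpy(dtype=np.float64)
    observed = ~np.isnan(labels)
    return PropertyDataset(smiles=df[smiles_column].tolist(), labels=labels,
                           observed=observed, task_type=task_type,
                           task_names=list(label_columns))


def load_corpus(path: str | Path, max_len: int | None = None) -> list[str]:
    """Read a one-SMILES-per-line corpus, dropping blank/unparsable/over-length
    entries with a logged count."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    out, dropped = [], 0
    for s in lines:
        if not s or Chem.MolFromSmiles(s) is None:
            dropped += 1
            continue
        if max_len is not None and len(tokenize(s)) > max_len:
            dropped += 1
            continue
        out.append(s)
    if dropped:
        logger.warning("dropped %d corpus lines (blank, unparsable or over-length)",
                       dropped)
    return out


# ---------------------------------------------------------------------------
# Scaffold and random splitting
# ---------------------------------------------------------------------------

def murcko_scaffold(s: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; acyclic molecules map to ''."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {s!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


@dataclass
class SplitAssignment:
    """Disjoint train/valid/test index sets covering a dataset."""

    train: list[int]
    valid: list[int]
    test: list[int]
    scaffold_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        parts = [set(self.train), set(self.valid), set(self.test)]
        if sum(len(p) for p in parts) != len(set().union(*parts)):
            raise ValueError("split subsets overlap")

    def to_frame(self, smiles: list[str]) -> pd.DataFrame:
        rows = [(i, smiles[i], name)
                for name, idx in (("train", self.train), ("valid", self.valid),
                                  ("test", self.test))
                for i in idx]
        return pd.DataFrame(rows, columns=["index", "smiles", "subset"])


def _check_fractions(fractions) -> tuple[float, float, float]:
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
        raise ValueError("fractions must be three positives summing to 1")
    return f


def scaffold_split(ds: PropertyDataset, fractions=(0.8, 0.1, 0.1),
                   seed: int = 0) -> SplitAssignment:
    """Greedy scaffold split: whole scaffold groups, largest first, are
    assigned to train until its target size is met, then valid, then test.

    Ties between equal-size groups break on the scaffold string, so the
    assignment is deterministic (the seed is accepted for interface symmetry
    with :func:`random_split` but does not influence the result).
    """
    f_train, f_valid, _ = _check_fractions(fractions)
    n = len(ds)
    if n < 3:
        raise ValueError("need at least 3 molecules to split")
    groups: dict[str, list[int]] = {}
    scaffold_of: dict[int, str] = {}
    for i, s in enumerate(ds.smiles):
        scaf = murcko_scaffold(s)
        scaffold_of[i] = scaf
        groups.setdefault(scaf, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n_train, n_valid = f_train * n, f_valid * n
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for _, idx in ordered:
        if len(train) + len(idx) <= n_train or not train:
            train.extend(idx)
        elif len(valid) + len(idx) <= n_valid or not valid:
            valid.extend(idx)
        else:
            test.extend(idx)
    if not test:  # degenerate: too few groups to fill three subsets
        raise ValueError("fewer than 3 scaffold groups; cannot form a 3-way split")
    return SplitAssignment(train=train, valid=valid, test=test,
                           scaffold_of=scaffold_of)


def random_split(ds: PropertyDataset, fractions=(0.8, 0.1, 0.1),
                 seed: int = 0) -> SplitAssignment:
    """Uniform shuffle under `seed`, then contiguous cuts at the fractions."""
    f_train, f_valid, _ = _check_fractions(fractions)
    n = len(ds)
    if n < 3:
        raise ValueError("need at least 3 molecules to split")
    order = np.random.default_rng(seed).permutation(n)
    c1 = int(round(f_train * n))
    c2 = c1 + int(round(f_valid * n))
    c1, c2 = min(c1, n - 2), min(c1 + max(1, c2 - c1), n - 1)
    return SplitAssignment(train=order[:c1].tolist(),
                           valid=order[c1:c2].tolist(),
                           test=order[c2:].tolist())
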