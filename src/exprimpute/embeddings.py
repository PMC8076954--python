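"""Learnable distributed representations of categorical covariates.

Each categorical covariate (tissue, sex, cohort, …) gets its own lookup
table W_j of shape (vocabulary × dimension); a sample's embedding is the
concatenation of the looked-up rows, appended to the numeric covariates as
model input. The embedding dimension follows the common rule of thumb
d = ⌊√v⌋ + 1, which assigns 8 dimensions to a 49-tissue vocabulary.
"""

from __future__ import annotations

import math

import numpy as np

from .datamodel import CovariateTable
from .nn import Embedding, Param


def embedding_dim(v: int) -> int:
    """Default embedding dimension for a vocabulary of size v: ⌊√v⌋ + 1."""
    if v < 1:
        raise ValueError(f"vocabulary size must be ≥ 1, got {v}")
    return math.isqrt(v) + 1


class EmbeddingTable:
    """One lookup table per categorical covariate, plus joint lookup.

    Separate instances are used wherever two networks must not share
    parameters (e.g. an adversarial generator and discriminator).
    """

    def __init__(
        self,
        vocab_sizes: list[int],
        rng: np.random.Generator,
        dims: list[int] | None = None,
        names: list[str] | None = None,
    ):
        self.dims = dims if dims is not None else [embedding_dim(v) for v in vocab_sizes]
        if len(self.dims) != len(vocab_sizes):
            raise ValueError("dims must match vocab_sizes")
        self.names = names or [f"cov{j}" for j in range(len(vocab_sizes))]
        self.tables = [Embedding(v, d, rng) for v, d in zip(vocab_sizes, self.dims)]

    @property
    def total_dim(self) -> int:
        return sum(self.dims)

    def params(self) -> list[Param]:
        return [t.W for t in self.tables]

    def forward(self, codes: np.ndarray) -> np.ndarray:
        """Concatenated embeddings for a (batch × covariates) code matrix."""
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        if codes.shape[1] != len(self.tables):
            raise ValueError(
                f"expected {len(self.tables)} categorical codes, got {codes.shape[1]}"
            )
        cols = []
        for j, table in enumerate(self.tables):
            col = codes[:, j]
            v = table.W.value.shape[0]
            if col.min(initial=1) < 1 or col.max(initial=1) > v:
                bad = col[(col < 1) | (col > v)][0]
                raise ValueError(
                    f"covariate {self.names[j]!r}: code {bad} outside vocabulary 1..{v}"
                )
            cols.append(table.forward(col))
        return np.concatenate(cols, axis=1)

    def backward(self, gy: np.ndarray) -> None:
        """Scatter the gradient of the concatenated embedding back to tables."""
        ofs = 0
        for table, d in zip(self.tables, self.dims):
            table.backward(gy[:, ofs : ofs + d])
            ofs += d

    def export(self, vocab: list[list[str]]):
        """(covariate name, label, vector) triples for TSV export."""
        rows = []
        for name, table, labels in zip(self.names, self.tables, vocab):
            for k, label in enumerate(labels):
                rows.append((name, label, table.W.value[k].copy()))
        return rows


def embed(q: np.ndarray, tables: EmbeddingTable) -> np.ndarray:
    """Embedding vector(s) for categorical code(s) q (1-based).

    Equivalent to concatenating one-hot(q_j)ᵀ W_j over covariates j.
    """
    q = np.asarray(q, dtype=np.int64)
    if q.ndim == 1:
        return tables.forward(q[None, :])[0]
    return tables.forward(q)


def embedding_dims_for(cov: CovariateTable) -> list[int]:
    return [embedding_dim(v) for v in cov.vocab_sizes]
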