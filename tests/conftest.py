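"""Shared fixtures: small hand-built and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from exprimpute.datamodel import CovariateTable, ExpressionMatrix, Mask, MaskedDataset
from exprimpute.synthdata import SynthConfig, generate_dataset


def make_dataset(
    values: np.ndarray,
    mask: np.ndarray,
    tissues: np.ndarray,
    donor_ids: list[str] | None = None,
    age: np.ndarray | None = None,
    tissue_vocab: list[str] | None = None,
) -> MaskedDataset:
    """Assemble a MaskedDataset from raw arrays for unit tests."""
    values = np.asarray(values, dtype=float)
    s, n = values.shape
    donor_ids = donor_ids or [f"D{i:03d}" for i in range(s)]
    tissue_vocab = tissue_vocab or ["blood", "brain", "lung"]
    expr = ExpressionMatrix(
        values,
        gene_ids=[f"G{g}" for g in range(n)],
        sample_ids=[f"{d}_{i}" for i, d in enumerate(donor_ids)],
        donor_ids=list(donor_ids),
    )
    sex = np.where(np.arange(s) % 2 == 0, 1, 2)
    age_arr = np.asarray(age, dtype=float) if age is not None else np.zeros(s)
    cov = CovariateTable(
        categorical_names=["tissue", "sex"],
        codes=np.stack([np.asarray(tissues), sex], axis=1),
        vocab=[tissue_vocab, ["female", "male"]],
        numeric_names=["age"],
        numeric=age_arr[:, None],
    )
    return MaskedDataset(expr, Mask(np.asarray(mask)), cov)


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic dataset + truth for fast model tests."""
    cfg = SynthConfig(n_genes=20, n_donors=60, latent_rank=4, seed=3)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
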