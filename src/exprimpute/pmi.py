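"""Pseudo-mask imputer (PMI): model, loss, training loop, and inference.

PMI is a self-supervised regressor. At each training step a *pseudo-mask*
hides a random subset of the observed entries of every sample; the network
receives the remaining (pseudo-observed) values together with the pseudo-mask
and the sample covariates, and is penalized — by mean squared error — only on
the hidden (pseudo-missing) entries. Because the pseudo-mask is redrawn per
example and step, the effective training set is greatly enlarged, and the
loss never rewards copying inputs to outputs. At inference the pseudo-mask
equals the real observation mask and the network predicts every gene; the
imputed sample keeps observed values untouched:

    x̂ = m ⊙ x~ + (1 − m) ⊙ f(x~, m, r, q)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import MaskedDataset
from .embeddings import EmbeddingTable
from .masking import MaskSamplerConfig, pseudo_split, sample_pseudo_mask
from .nn import MLP, Adam, get_state, set_state

logger = logging.getLogger(__name__)


@dataclass
class PMIConfig:
    """Training hyperparameters for the pseudo-mask imputer.

    ``hidden=None`` picks two layers of ``min(2048, 4·n_genes)`` units.
    """

    hidden: tuple[int, ...] | None = None
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 30
    lr_decay_patience: int = 10  # halve the learning rate after this many flat epochs
    min_lr: float = 1e-5
    mask_cfg: MaskSamplerConfig = field(default_factory=lambda: MaskSamplerConfig(0.4, 0.6))
    batch_norm: bool = False
    seed: int = 0

    def resolve_hidden(self, n_genes: int) -> tuple[int, ...]:
        if self.hidden is not None:
            return tuple(self.hidden)
        h = min(2048, 4 * n_genes)
        return (h, h)


class PMIModel:
    """Trained PMI state: MLP, embedding tables, config, and schemas."""

    def __init__(
        self,
        n_genes: int,
        n_numeric: int,
        vocab_sizes: list[int],
        config: PMIConfig,
        rng: np.random.Generator,
        covariate_names: list[str] | None = None,
    ):
        self.n_genes = n_genes
        self.n_numeric = n_numeric
        self.vocab_sizes = list(vocab_sizes)
        self.config = config
        self.embeddings = EmbeddingTable(vocab_sizes, rng, names=covariate_names)
        n_in = 2 * n_genes + n_numeric + self.embeddings.total_dim
        self.mlp = MLP(
            n_in, config.resolve_hidden(n_genes), n_genes, rng, batch_norm=config.batch_norm
        )
        self.gene_ids: list[str] | None = None
        self.standardization: dict | None = None  # gene_means/gene_sds reference

    def params(self):
        return self.mlp.params() + self.embeddings.params()

    def forward(
        self,
        x_in: np.ndarray,
        mask_in: np.ndarray,
        r: np.ndarray,
        q: np.ndarray,
        train: bool = False,
    ) -> np.ndarray:
        e = self.embeddings.forward(q)
        z = np.concatenate([x_in * mask_in, mask_in, r, e], axis=1)
        return self.mlp.forward(z, train)

    def backward(self, g_out: np.ndarray) -> None:
        g_in = self.mlp.backward(g_out)
        self.embeddings.backward(g_in[:, -self.embeddings.total_dim :])

    def state(self):
        return get_state(self.mlp) + [p.value.copy() for p in self.embeddings.params()]

    def load_state(self, state) -> None:
        n_mlp = len(get_state(self.mlp))
        set_state(self.mlp, state[:n_mlp])
        for p, v in zip(self.embeddings.params(), state[n_mlp:]):
            p.value[...] = v


def pmi_forward(
    x_in: np.ndarray, mask_in: np.ndarray, r: np.ndarray, q: np.ndarray, model: PMIModel
) -> np.ndarray:
    """Inference-mode forward pass; accepts single rows or batches."""
    single = np.asarray(x_in).ndim == 1
    x2 = np.atleast_2d(np.asarray(x_in, dtype=float))
    m2 = np.atleast_2d(np.asarray(mask_in, dtype=float))
    r2 = np.atleast_2d(np.asarray(r, dtype=float))
    q2 = np.atleast_2d(np.asarray(q, dtype=np.int64))
    out = model.forward(x2, m2, r2, q2, train=False)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite imputer output")
    return out[0] if single else out


def pmi_loss(
    x_bar: np.ndarray, y_tilde: np.ndarray, m: np.ndarray, m_tilde: np.ndarray
) -> float:
    """Mean squared error over pseudo-missing components only.

    Per row: L = Σ_i w_i (x̄_i − y~_i)² / Z with w = m ⊙ (1 − m~) and
    Z = Σ w. Rows without pseudo-missing components carry zero weight (no
    division by zero); the batch value is the mean over rows with Z > 0.
    """
    loss, _, n_valid = _pmi_loss_grad(
        np.atleast_2d(x_bar), np.atleast_2d(y_tilde), np.atleast_2d(m), np.atleast_2d(m_tilde)
    )
    if n_valid == 0:
        return 0.0
    return float(loss)


def _pmi_loss_grad(x_bar, y_tilde, m, m_tilde):
    """Batch loss, gradient wrt x̄, and the number of contributing rows."""
    w = (m * (1 - m_tilde)).astype(float)
    z = w.sum(axis=1)
    valid = z > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(x_bar), 0
    diff = (x_bar - y_tilde) * w
    per_row = np.zeros_like(z)
    np.divide((diff**2).sum(axis=1), z, out=per_row, where=valid)
    grad = np.zeros_like(x_bar)
    grad[valid] = 2.0 * diff[valid] / z[valid, None] / n_valid
    return per_row[valid].mean(), grad, n_valid


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _validation_pseudo_masks(mask: np.ndarray, cfg: MaskSamplerConfig, seed: int):
    """Fixed pseudo-masks so validation loss is comparable across epochs."""
    rng = np.random.default_rng(seed)
    return sample_pseudo_mask(mask, cfg, rng)


def train_pmi(
    train: MaskedDataset, val: MaskedDataset, config: PMIConfig | None = None
) -> tuple[PMIModel, TrainingLog]:
    """Train a PMI model with Adam and early stopping on validation loss.

    Per step: sample a batch, draw fresh pseudo-masks over the observed
    entries, split into pseudo-observed inputs and pseudo-missing targets,
    forward with the *pseudo*-mask in the mask slot, and take one Adam step on
    the masked MSE. Validation uses a fixed, seeded set of pseudo-masks;
    training stops after ``patience`` epochs without improvement and the
    best-validation parameters are restored.
    """
    config = config or PMIConfig()
    if config.mask_cfg.alpha >= 1.0:
        warnings.warn(
            "alpha = beta = 1 leaves no pseudo-missing components; "
            "training cannot make any parameter updates",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    n = train.n_genes
    model = PMIModel(
        n,
        train.covariates.n_numeric,
        train.covariates.vocab_sizes,
        config,
        rng,
        covariate_names=train.covariates.categorical_names,
    )
    model.gene_ids = list(train.expression.gene_ids)
    opt = Adam(model.params(), lr=config.learning_rate)

    x_tr = train.observed_values()
    m_tr = train.mask.values.astype(float)
    r_tr, q_tr = train.covariates.numeric, train.covariates.codes

    x_va = val.observed_values()
    m_va = val.mask.values
    mt_va = _validation_pseudo_masks(m_va, config.mask_cfg, config.seed + 10_007)
    xv_in, yv = pseudo_split(x_va, m_va, mt_va)

    log = TrainingLog()
    best_state, best_loss, stale = None, np.inf, 0
    for epoch in range(config.max_epochs):
        epoch_losses = []
        for idx in _batches(train.n_samples, config.batch_size, rng):
            m_b = train.mask.values[idx]
            mt_b = sample_pseudo_mask(m_b, config.mask_cfg, rng)
            x_in, y_b = pseudo_split(x_tr[idx], m_b, mt_b)
            opt.zero_grad()
            x_bar = model.forward(
                x_in, mt_b.astype(float), r_tr[idx], q_tr[idx], train=True
            )
            loss, grad, n_valid = _pmi_loss_grad(x_bar, y_b, m_b, mt_b)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            if n_valid == 0:
                continue
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        log.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)

        x_bar_v = model.forward(xv_in, mt_va.astype(float), val.covariates.numeric, val.covariates.codes)
        v_loss = pmi_loss(x_bar_v, yv, m_va, mt_va)
        log.val_loss.append(v_loss)
        if v_loss < best_loss - 1e-12:
            best_loss, best_state, stale = v_loss, model.state(), 0
            log.best_epoch = epoch
        else:
            stale += 1
            if (
                config.lr_decay_patience
                and stale % config.lr_decay_patience == 0
                and opt.lr > config.min_lr
            ):
                opt.lr = max(opt.lr * 0.5, config.min_lr)
            if stale >= config.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, log.best_epoch)
                break
    if best_state is not None:
        model.load_state(best_state)
    return model, log


def pmi_impute(data: MaskedDataset, model: PMIModel):
    """Impute missing entries: x̂ = m ⊙ x~ + (1 − m) ⊙ f(x~, m, r, q).

    At inference the pseudo-mask equals the observation mask (keep
    probability 1), and observed entries pass through bit-exactly.
    """
    x_in = data.observed_values()
    m = data.mask.values.astype(float)
    x_bar = pmi_forward(x_in, m, data.covariates.numeric, data.covariates.codes, model)
    x_hat = np.where(data.mask.values == 1, x_in, x_bar)
    return replace(data.expression, values=x_hat)
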