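"""Adversarial imputer (GAIN family): generator, discriminator, and training.

The generator fills in missing expression values from the observed entries,
masked noise, the mask, and the sample covariates. The discriminator receives
the composed sample (observed values + generated values) together with a
*hint* vector — which reveals the true observed/imputed status of a random
subset of genes and is 0.5 elsewhere — and predicts, per gene, the probability
that the value was observed rather than generated. Genes whose status was
revealed by the hint are excluded from both losses.

The MSE-only ablation ("gain_mse") drops the adversarial terms entirely — no
discriminator is ever instantiated — and trains the generator on the squared
reconstruction error of entries with known truth. Since the adversarial
contribution is typically small, MSE-only is the default mode; the full
adversarial game sits behind ``adversarial=True``.

Both modes can hide a random subset of the *observed* entries from the
generator's input (``pseudo_mask_inputs``, on by default): without it the
squared-error term supervises only reconstruction of values the generator
already sees, providing no direct signal on predicting genuinely absent
entries (and making the fully observed training sets of the inductive
scenario degenerate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import MaskedDataset
from .embeddings import EmbeddingTable
from .masking import MaskSamplerConfig, sample_hint, sample_pseudo_mask
from .nn import MLP, Adam, get_state, set_state, sigmoid

logger = logging.getLogger(__name__)

#: probabilities are clipped to [EPS, 1−EPS] before any logarithm
EPS = 1e-7


@dataclass(frozen=True)
class NoiseConfig:
    """Fixed noise source for the generator (original-GAIN convention)."""

    dist: str = "uniform"  # "uniform" or "normal"
    low: float = 0.0
    high: float = 0.01
    mean: float = 0.0
    sd: float = 0.01


@dataclass
class GainConfig:
    hidden: tuple[int, ...] | None = None
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 50
    lr_decay_patience: int = 10  # halve the generator/discriminator lr when flat
    min_lr: float = 1e-5
    lam: float = 10.0  # weight of the reconstruction MSE in the generator loss
    adversarial: bool = False  # False = MSE-only mode (no discriminator)
    pseudo_mask_inputs: bool = True
    hint_cfg: MaskSamplerConfig = field(default_factory=lambda: MaskSamplerConfig(0.8, 0.99))
    pseudo_cfg: MaskSamplerConfig = field(default_factory=lambda: MaskSamplerConfig(0.3, 0.6))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    batch_norm: bool = False
    seed: int = 0

    def resolve_hidden(self, n_genes: int) -> tuple[int, ...]:
        if self.hidden is not None:
            return tuple(self.hidden)
        h = min(2048, 4 * n_genes)
        return (h, h)


class GainModel:
    """Generator (+ optional discriminator) with independent embedding sets."""

    def __init__(
        self,
        n_genes: int,
        n_numeric: int,
        vocab_sizes: list[int],
        config: GainConfig,
        rng: np.random.Generator,
        covariate_names: list[str] | None = None,
    ):
        self.n_genes = n_genes
        self.n_numeric = n_numeric
        self.vocab_sizes = list(vocab_sizes)
        self.config = config
        hidden = config.resolve_hidden(n_genes)
        self.emb_g = EmbeddingTable(vocab_sizes, rng, names=covariate_names)
        g_in = 3 * n_genes + n_numeric + self.emb_g.total_dim
        self.generator = MLP(g_in, hidden, n_genes, rng, batch_norm=config.batch_norm)
        if config.adversarial:
            self.emb_d = EmbeddingTable(vocab_sizes, rng, names=covariate_names)
            d_in = 2 * n_genes + n_numeric + self.emb_d.total_dim
            self.discriminator = MLP(d_in, hidden, n_genes, rng, batch_norm=config.batch_norm)
        else:
            self.emb_d = None
            self.discriminator = None
        self.gene_ids: list[str] | None = None
        self.standardization: dict | None = None

    def generator_params(self):
        return self.generator.params() + self.emb_g.params()

    def discriminator_params(self):
        if self.discriminator is None:
            return []
        return self.discriminator.params() + self.emb_d.params()

    # -- forward/backward helpers -------------------------------------------
    def g_forward(self, x_t, z_t, m, r, q, train=False):
        e = self.emb_g.forward(q)
        z = np.concatenate([x_t, z_t, m, r, e], axis=1)
        return self.generator.forward(z, train)

    def g_backward(self, g_out):
        g_in = self.generator.backward(g_out)
        self.emb_g.backward(g_in[:, -self.emb_g.total_dim :])

    def d_forward(self, x_hat, h, r, q, train=False):
        """Raw discriminator logits (one per gene)."""
        e = self.emb_d.forward(q)
        z = np.concatenate([x_hat, h, r, e], axis=1)
        return self.discriminator.forward(z, train)

    def d_backward(self, g_out):
        """Backprop through the discriminator; returns the gradient wrt x̂."""
        g_in = self.discriminator.backward(g_out)
        self.emb_d.backward(g_in[:, -self.emb_d.total_dim :])
        return g_in[:, : self.n_genes]

    def state(self):
        s = get_state(self.generator) + [p.value.copy() for p in self.emb_g.params()]
        if self.discriminator is not None:
            s += get_state(self.discriminator)
            s += [p.value.copy() for p in self.emb_d.params()]
        return s

    def load_state(self, state):
        i = len(get_state(self.generator))
        set_state(self.generator, state[:i])
        for p in self.emb_g.params():
            p.value[...] = state[i]
            i += 1
        if self.discriminator is not None:
            j = i + len(get_state(self.discriminator))
            set_state(self.discriminator, state[i:j])
            for p in self.emb_d.params():
                p.value[...] = state[j]
                j += 1


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def sample_noise(
    n: int, m: np.ndarray, noise_cfg: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Masked noise z~ = z ⊙ (1 − m): zero at observed positions.

    Masking keeps a bijective association between noise components and genes.
    """
    m = np.asarray(m)
    shape = m.shape if m.ndim > 1 else (n,)
    if noise_cfg.dist == "uniform":
        z = rng.uniform(noise_cfg.low, noise_cfg.high, size=shape)
    elif noise_cfg.dist == "normal":
        z = rng.normal(noise_cfg.mean, noise_cfg.sd, size=shape)
    else:
        raise ValueError(f"unknown noise distribution {noise_cfg.dist!r}")
    return z * (1 - m)


def generate(x_t, z_t, m, r, q, model: GainModel) -> np.ndarray:
    """Inference-mode generator output x̄ = G(x⊙m, z⊙(1−m), m, r, q)."""
    single = np.asarray(x_t).ndim == 1
    args = [np.atleast_2d(np.asarray(a, dtype=float)) for a in (x_t, z_t, m, r)]
    q2 = np.atleast_2d(np.asarray(q, dtype=np.int64))
    out = model.g_forward(*args, q2, train=False)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite generator output")
    return out[0] if single else out


def compose_imputed(x_t: np.ndarray, x_bar: np.ndarray, m: np.ndarray) -> np.ndarray:
    """x̂ = m ⊙ x~ + (1 − m) ⊙ x̄: observed values pass through exactly."""
    m = np.asarray(m)
    return np.where(m == 1, x_t, x_bar)


def discriminate(x_hat, h, r, q, model: GainModel) -> np.ndarray:
    """Per-gene probability of being observed, clipped to [ε, 1−ε]."""
    single = np.asarray(x_hat).ndim == 1
    args = [np.atleast_2d(np.asarray(a, dtype=float)) for a in (x_hat, h, r)]
    q2 = np.atleast_2d(np.asarray(q, dtype=np.int64))
    y = np.clip(sigmoid(model.d_forward(*args, q2, train=False)), EPS, 1 - EPS)
    return y[0] if single else y


def discriminator_loss(m: np.ndarray, y_hat: np.ndarray, b: np.ndarray) -> float:
    """Masked binary cross-entropy over genes whose status was not leaked.

    L_D = −(1/Z) Σ_{i: b_i=0} [ m_i log ŷ_i + (1−m_i) log(1−ŷ_i) ],
    Z = 1 + (1−b)ᵀ(1−b). Revealed genes (b_i = 1) contribute exactly zero.
    Row inputs or batches; batches return the row mean.
    """
    m2, y2, b2 = np.atleast_2d(m), np.atleast_2d(y_hat), np.atleast_2d(b)
    y2 = np.clip(y2, EPS, 1 - EPS)
    w = (1 - b2).astype(float)
    z = 1.0 + w.sum(axis=1)
    ll = w * (m2 * np.log(y2) + (1 - m2) * np.log(1 - y2))
    return float((-ll.sum(axis=1) / z).mean())


def generator_loss(m, x, x_bar, y_hat, b, lam: float) -> float:
    """Adversarial + reconstruction loss of the generator.

    L_G = −(1/Z1) Σ_{i: b_i=0, m_i=0} log ŷ_i + (λ/Z2) Σ_{i: m_i=1} (x_i−x̄_i)²
    with Z1 = 1 + (1−b)ᵀ(1−b) and Z2 = mᵀm (MSE term defined as 0 when Z2=0).
    """
    m2, x2, xb2, y2, b2 = (np.atleast_2d(a) for a in (m, x, x_bar, y_hat, b))
    y2 = np.clip(y2, EPS, 1 - EPS)
    w_adv = ((1 - b2) * (1 - m2)).astype(float)
    z1 = 1.0 + (1 - b2).astype(float).sum(axis=1)
    adv = -(w_adv * np.log(y2)).sum(axis=1) / z1
    z2 = m2.astype(float).sum(axis=1)
    sse = (m2 * (x2 - xb2) ** 2).sum(axis=1)
    mse = np.divide(sse, z2, out=np.zeros_like(sse, dtype=float), where=z2 > 0)
    return float((adv + lam * mse).mean())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainingLog:
    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _effective_mask(m_b, config, rng):
    """Mask shown to the generator: a pseudo-sub-mask of the observed entries
    when pseudo-masking is enabled, else the true mask."""
    if config.pseudo_mask_inputs:
        return sample_pseudo_mask(m_b, config.pseudo_cfg, rng)
    return m_b


def _mse_grad(x, x_bar, m_truth):
    """Reconstruction MSE over entries with known truth, and its x̄ gradient."""
    w = m_truth.astype(float)
    z = w.sum(axis=1)
    valid = z > 0
    diff = (x_bar - x) * w
    per_row = np.divide((diff**2).sum(axis=1), z, out=np.zeros_like(z), where=valid)
    grad = np.zeros_like(x_bar)
    grad[valid] = 2.0 * diff[valid] / z[valid, None]
    n_rows = x.shape[0]
    return per_row.mean(), grad / n_rows


def train_gain(
    train: MaskedDataset, val: MaskedDataset, config: GainConfig | None = None
) -> tuple[GainModel, TrainingLog]:
    """Train a GAIN-family model; returns the best-validation checkpoint.

    In adversarial mode each batch takes one discriminator update followed by
    one generator update (1:1 interleaving); in MSE-only mode the generator
    takes plain squared-error steps and no discriminator exists. Early
    stopping watches a fixed-seed validation imputation MSE with the
    configured patience.
    """
    config = config or GainConfig()
    rng = np.random.default_rng(config.seed)
    n = train.n_genes
    model = GainModel(
        n,
        train.covariates.n_numeric,
        train.covariates.vocab_sizes,
        config,
        rng,
        covariate_names=train.covariates.categorical_names,
    )
    model.gene_ids = list(train.expression.gene_ids)
    opt_g = Adam(model.generator_params(), lr=config.learning_rate)
    opt_d = (
        Adam(model.discriminator_params(), lr=config.learning_rate)
        if config.adversarial
        else None
    )

    x_tr = train.observed_values()
    r_tr, q_tr = train.covariates.numeric, train.covariates.codes

    # fixed validation draws: pseudo-mask and noise, for comparable epochs
    val_rng = np.random.default_rng(config.seed + 20_011)
    m_va = val.mask.values
    me_va = _effective_mask(m_va, config, val_rng)
    x_va = val.observed_values()
    z_va = sample_noise(n, me_va, config.noise, val_rng)
    rv, qv = val.covariates.numeric, val.covariates.codes
    # score prediction of entries whose truth is known but hidden from input;
    # if none are hidden (pure reconstruction), score the observed entries
    w_va = (m_va * (1 - me_va)).astype(float)
    if w_va.sum() == 0:
        w_va = m_va.astype(float)

    def val_mse() -> float:
        x_bar = model.g_forward(
            x_va * me_va, z_va, me_va.astype(float), rv, qv, train=False
        )
        return float((w_va * (x_bar - x_va) ** 2).sum() / w_va.sum())

    log = TrainingLog()
    best_loss = val_mse()
    best_state, stale = model.state(), 0
    log.best_epoch = -1

    for epoch in range(config.max_epochs):
        d_losses, g_losses = [], []
        for idx in _batches(train.n_samples, config.batch_size, rng):
            m_b = train.mask.values[idx]
            x_b = x_tr[idx]
            r_b, q_b = r_tr[idx], q_tr[idx]

            if config.adversarial:
                # ---- discriminator step ----
                me = _effective_mask(m_b, config, rng)
                z_t = sample_noise(n, me, config.noise, rng)
                x_t = x_b * me
                x_bar = model.g_forward(x_t, z_t, me.astype(float), r_b, q_b, train=True)
                x_hat = compose_imputed(x_t, x_bar, me)
                hint = sample_hint(me, config.hint_cfg, rng)
                opt_d.zero_grad()
                logits = model.d_forward(x_hat, hint.h, r_b, q_b, train=True)
                y_hat = sigmoid(logits)
                d_losses.append(discriminator_loss(me, y_hat, hint.b))
                w = (1 - hint.b).astype(float)
                z_norm = 1.0 + w.sum(axis=1, keepdims=True)
                g_logits = w * (y_hat - me) / z_norm / m_b.shape[0]
                model.d_backward(g_logits)
                opt_d.step()

            # ---- generator step ----
            me = _effective_mask(m_b, config, rng)
            z_t = sample_noise(n, me, config.noise, rng)
            x_t = x_b * me
            opt_g.zero_grad()
            x_bar = model.g_forward(x_t, z_t, me.astype(float), r_b, q_b, train=True)
            # truth is known exactly where the *true* mask is 1
            mse, g_xbar = _mse_grad(x_b, x_bar, m_b)
            g_loss = config.lam * mse if config.adversarial else mse
            g_xbar = (config.lam if config.adversarial else 1.0) * g_xbar
            if config.adversarial:
                x_hat = compose_imputed(x_t, x_bar, me)
                hint = sample_hint(me, config.hint_cfg, rng)
                for p in model.discriminator_params():
                    p.grad[...] = 0.0
                logits = model.d_forward(x_hat, hint.h, r_b, q_b, train=True)
                y_hat = np.clip(sigmoid(logits), EPS, 1 - EPS)
                w_adv = ((1 - hint.b) * (1 - me)).astype(float)
                z1 = 1.0 + (1 - hint.b).astype(float).sum(axis=1, keepdims=True)
                g_loss += float(
                    (-(w_adv * np.log(y_hat)).sum(axis=1) / z1[:, 0]).mean()
                )
                # d(−log σ(l))/dl = σ(l) − 1 on the penalized entries
                g_logits = w_adv * (y_hat - 1.0) / z1 / m_b.shape[0]
                g_xhat = model.d_backward(g_logits)
                g_xbar = g_xbar + g_xhat * (1 - me)
            if not np.isfinite(g_loss):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}: {g_loss}"
                )
            model.g_backward(g_xbar)
            opt_g.step()
            g_losses.append(g_loss)

        log.g_loss.append(float(np.mean(g_losses)) if g_losses else np.nan)
        log.d_loss.append(float(np.mean(d_losses)) if d_losses else np.nan)
        v = val_mse()
        log.val_loss.append(v)
        if v < best_loss - 1e-12:
            best_loss, best_state, stale = v, model.state(), 0
            log.best_epoch = epoch
        else:
            stale += 1
            if (
                config.lr_decay_patience
                and stale % config.lr_decay_patience == 0
                and opt_g.lr > config.min_lr
            ):
                opt_g.lr = max(opt_g.lr * 0.5, config.min_lr)
                if opt_d is not None:
                    opt_d.lr = max(opt_d.lr * 0.5, config.min_lr)
            if stale >= config.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, log.best_epoch)
                break
    model.load_state(best_state)
    return model, log


def gain_impute(
    data: MaskedDataset, model: GainModel, rng: np.random.Generator, n_draws: int = 1
):
    """Impute x̂ = m ⊙ x~ + (1 − m) ⊙ x̄, optionally averaging x̄ over noise draws."""
    x_t = data.observed_values()
    m = data.mask.values
    r, q = data.covariates.numeric, data.covariates.codes
    acc = np.zeros_like(x_t)
    for _ in range(max(1, n_draws)):
        z_t = sample_noise(data.n_genes, m, model.config.noise, rng)
        acc += generate(x_t, z_t, m.astype(float), r, q, model)
    x_bar = acc / max(1, n_draws)
    x_hat = np.where(m == 1, x_t, x_bar)
    return replace(data.expression, values=x_hat)
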