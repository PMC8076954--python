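"""Stochastic mask machinery: MCAR masks, pseudo-masks, and hint vectors.

Three related samplers share one convention: a keep-probability ``p`` is drawn
once per sample row from U(α, β), then a Bernoulli(p) vector ``b`` is drawn
i.i.d. over genes. The pseudo-mask hides a random subset of *observed* entries
to create self-supervision targets; the hint vector leaks the true
observed/imputed status of a random subset of genes to the adversarial
discriminator (0.5 marks "status withheld").

All samplers take an explicit ``numpy.random.Generator`` — there is no global
RNG state anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Mask


@dataclass(frozen=True)
class MaskSamplerConfig:
    """Bounds of the U(α, β) keep-probability distribution.

    Defaults favour dense pseudo-observed vectors (low bias, slower
    convergence); hint sampling typically uses a higher α so most mask bits
    are revealed to the discriminator.
    """

    alpha: float = 0.5
    beta: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= self.beta <= 1.0):
            raise ValueError(f"need 0 ≤ alpha ≤ beta ≤ 1, got ({self.alpha}, {self.beta})")


@dataclass
class HintVector:
    """Per-gene discriminator hint: h = b⊙m + ½(1−b), so h ∈ {0, ½, 1}ⁿ."""

    h: np.ndarray
    b: np.ndarray


def _as_2d(a: np.ndarray) -> tuple[np.ndarray, bool]:
    a = np.asarray(a)
    if a.ndim == 1:
        return a[None, :], True
    return a, False


def _draw_bernoulli(
    shape: tuple[int, int], cfg: MaskSamplerConfig, rng: np.random.Generator
) -> np.ndarray:
    """b with one p ~ U(α, β) per row, entries i.i.d. Bernoulli(p)."""
    p = rng.uniform(cfg.alpha, cfg.beta, size=(shape[0], 1))
    return (rng.random(shape) < p).astype(np.int8)


def sample_mcar_mask(
    n_samples: int, n_genes: int, missing_rate: float, rng: np.random.Generator
) -> Mask:
    """I.i.d. Bernoulli(1 − missing_rate) observation mask.

    Missing-completely-at-random: independent of expression values and
    covariates by construction.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    return Mask((rng.random((n_samples, n_genes)) >= missing_rate).astype(np.int8))


def sample_pseudo_mask(
    m: np.ndarray, cfg: MaskSamplerConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pseudo-mask m~ = m ⊙ b; a sub-mask of the observed entries.

    Accepts a single mask row or a (rows × genes) matrix; ``p`` is drawn
    independently per row so every example gets a different pseudo-observed
    set.
    """
    m2, was_1d = _as_2d(m)
    b = _draw_bernoulli(m2.shape, cfg, rng)
    mt = (m2 * b).astype(np.int8)
    return mt[0] if was_1d else mt


def pseudo_split(
    x: np.ndarray, m: np.ndarray, m_tilde: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split observed values into pseudo-observed x~ and pseudo-missing y~.

    x~ = x ⊙ m~ (model input) and y~ = x ⊙ m ⊙ (1 − m~) (regression target);
    their supports are disjoint and x~ + y~ = x ⊙ m.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m)
    m_tilde = np.asarray(m_tilde)
    if np.any(m_tilde > m):
        raise ValueError("pseudo-mask must satisfy m~ ≤ m elementwise")
    x_obs = np.where(m == 1, x, 0.0)  # never read values at m == 0
    x_t = x_obs * m_tilde
    y_t = x_obs * (1 - m_tilde)
    return x_t, y_t


def sample_hint(
    m: np.ndarray, cfg: MaskSamplerConfig, rng: np.random.Generator
) -> HintVector:
    """Hint h = b⊙m + ½(1−b): reveals m_i where b_i = 1, 0.5 elsewhere."""
    m2, was_1d = _as_2d(m)
    b = _draw_bernoulli(m2.shape, cfg, rng)
    h = b * m2 + 0.5 * (1 - b)
    if was_1d:
        return HintVector(h[0], b[0])
    return HintVector(h, b)


def write_mask(mask: Mask, path) -> None:
    """Dump a mask as a TSV of 0/1 for reproducibility."""
    np.savetxt(path, mask.values, fmt="%d", delimiter="\t")


def read_mask(path) -> Mask:
    return Mask(np.loadtxt(path, delimiter="\t", ndmin=2).astype(np.int8))
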