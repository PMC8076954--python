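"""Reference imputers: tissue-median, surrogate-tissue, and k-NN.

These are the classical comparators for the neural imputers. On standardized
data the tissue median is a near-zero-R² anchor; surrogate-tissue imputation
(filling a donor's missing tissue with the same donor's measurement in an
accessible tissue such as whole blood) is typically *worse* than the median
unless cross-tissue correlation is strong; k-NN provides a solid
nonparametric baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import ExpressionMatrix, MaskedDataset

logger = logging.getLogger(__name__)


@dataclass
class MedianTable:
    """Per-(tissue, gene) medians of observed training values.

    ``medians[t, g]`` is NaN when tissue t never observes gene g; the global
    per-gene median serves as fallback (0 — the standardized-scale center —
    when a gene has no observation at all).
    """

    tissue_vocab: list[str]
    medians: np.ndarray  # (n_tissues, n_genes), NaN where unobserved
    global_medians: np.ndarray  # (n_genes,)

    def lookup(self, tissue_codes: np.ndarray) -> np.ndarray:
        """Median matrix aligned to samples, with fallbacks applied."""
        out = self.medians[np.asarray(tissue_codes) - 1].copy()
        nan = np.isnan(out)
        if nan.any():
            out[nan] = np.broadcast_to(self.global_medians, out.shape)[nan]
        return out


def fit_medians(data: MaskedDataset, tissue_covariate: str = "tissue") -> MedianTable:
    """Fit per-(tissue, gene) medians on the observed entries of ``data``."""
    codes = data.covariates.column(tissue_covariate)
    j = data.covariates.categorical_names.index(tissue_covariate)
    vocab = data.covariates.vocab[j]
    x = np.where(data.mask.values == 1, data.expression.values, np.nan)
    n_t, n_g = len(vocab), data.n_genes
    med = np.full((n_t, n_g), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices are expected
        for t in range(n_t):
            rows = codes == t + 1
            if rows.any():
                med[t] = np.nanmedian(x[rows], axis=0)
        glob = np.nanmedian(x, axis=0)
    never = np.isnan(glob)
    if never.any():
        logger.warning(
            "%d gene(s) without any observation; falling back to 0", int(never.sum())
        )
        glob[never] = 0.0
    return MedianTable(list(vocab), med, glob)


def median_impute(
    data: MaskedDataset, medians: MedianTable, tissue_covariate: str = "tissue"
) -> ExpressionMatrix:
    """Fill missing entries with the fitted (tissue, gene) median."""
    fill = medians.lookup(data.covariates.column(tissue_covariate))
    x_hat = np.where(data.mask.values == 1, data.observed_values(), fill)
    return replace(data.expression, values=x_hat)


def surrogate_impute(
    data: MaskedDataset,
    surrogate_tissue_label: str,
    tissue_covariate: str = "tissue",
    medians: MedianTable | None = None,
) -> ExpressionMatrix:
    """Fill a donor's missing values with their own surrogate-tissue values.

    For every missing (donor, tissue, gene) entry, look up the same donor's
    observed value of that gene in the surrogate tissue (e.g. whole blood).
    When the donor lacks a surrogate sample, or the surrogate value is itself
    missing, fall back to the (tissue, gene) median (fitted on ``data`` if
    not supplied). Fallback usage is counted and logged.
    """
    j = data.covariates.categorical_names.index(tissue_covariate)
    vocab = data.covariates.vocab[j]
    if surrogate_tissue_label not in vocab:
        raise ValueError(
            f"surrogate tissue {surrogate_tissue_label!r} not in vocabulary {vocab}"
        )
    surr_code = vocab.index(surrogate_tissue_label) + 1
    codes = data.covariates.column(tissue_covariate)
    donors = np.asarray(data.expression.donor_ids, dtype=object)

    # donor -> row index of their surrogate-tissue sample (first if several)
    surr_rows: dict[str, int] = {}
    for i in np.flatnonzero(codes == surr_code):
        surr_rows.setdefault(donors[i], int(i))

    medians = medians if medians is not None else fit_medians(data, tissue_covariate)
    fill = medians.lookup(codes)  # fallback layer
    x_obs = data.observed_values()
    m = data.mask.values
    x_hat = np.where(m == 1, x_obs, fill)

    n_fallback = 0
    for i in range(data.n_samples):
        miss = m[i] == 0
        if not miss.any():
            continue
        s = surr_rows.get(donors[i])
        if s is None or s == i:
            n_fallback += int(miss.sum())
            continue
        usable = miss & (m[s] == 1)
        x_hat[i, usable] = x_obs[s, usable]
        n_fallback += int((miss & ~usable).sum())
    if n_fallback:
        logger.info("surrogate imputation used the median fallback %d times", n_fallback)
    return replace(data.expression, values=x_hat)


def _pairwise_mean_sq_dist(
    xq: np.ndarray, mq: np.ndarray, xr: np.ndarray, mr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared difference over co-observed components, plus co-counts."""
    xq_o, xr_o = xq * mq, xr * mr
    counts = mq @ mr.T
    sq = (xq_o**2) @ mr.T - 2.0 * xq_o @ xr_o.T + mq @ (xr_o**2).T
    dist = np.full(sq.shape, np.inf)
    np.divide(sq, counts, out=dist, where=counts > 0)
    return dist, counts


def knn_impute(
    data: MaskedDataset,
    k: int,
    reference: MaskedDataset,
    medians: MedianTable | None = None,
    tissue_covariate: str = "tissue",
) -> ExpressionMatrix:
    """k-nearest-neighbour imputation against a reference set.

    Distance is the mean squared difference over components observed in both
    the query and the candidate; each missing gene is imputed as the
    unweighted mean of the gene's observed values among the k nearest
    neighbours that observe it. Ties break deterministically by reference
    row order. When the reference is the dataset itself, a sample is never
    its own neighbour. Queries sharing no observed component with any
    candidate (or genes unobserved among the k neighbours) fall back to the
    median, logged.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if reference.n_samples == 0:
        raise ValueError("reference must be nonempty")
    xq, mq = data.observed_values(), data.mask.values.astype(float)
    xr, mr = reference.observed_values(), reference.mask.values.astype(float)
    dist, counts = _pairwise_mean_sq_dist(xq, mq, xr, mr)
    if reference is data or (
        reference.expression.sample_ids == data.expression.sample_ids
        and reference.n_samples == data.n_samples
    ):
        np.fill_diagonal(dist, np.inf)

    medians = medians if medians is not None else fit_medians(reference, tissue_covariate)
    fill = medians.lookup(data.covariates.column(tissue_covariate))
    x_hat = np.where(data.mask.values == 1, xq, fill)

    order = np.lexsort((np.arange(dist.shape[1])[None, :].repeat(dist.shape[0], 0), dist), axis=1)
    n_fallback_rows = 0
    for i in range(data.n_samples):
        miss = data.mask.values[i] == 0
        if not miss.any():
            continue
        cand = order[i][np.isfinite(dist[i][order[i]])][:k]
        if cand.size == 0:
            n_fallback_rows += 1
            continue
        obs_counts = mr[cand].sum(axis=0)
        sums = (xr[cand] * mr[cand]).sum(axis=0)
        have = miss & (obs_counts > 0)
        x_hat[i, have] = sums[have] / obs_counts[have]
    if n_fallback_rows:
        logger.info("k-NN fell back to the median for %d sample(s)", n_fallback_rows)
    return replace(data.expression, values=x_hat)
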