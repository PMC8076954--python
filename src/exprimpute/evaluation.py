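"""Evaluation protocol: per-gene R², scenario runners, and missing-rate sweeps.

Evaluation draws an MCAR mask over the *observed* entries of the test data
(truth is needed for scoring), hands the imputer a dataset in which those
entries are hidden — and poisoned with NaN, so any method that illegally reads
them fails loudly — and scores each gene by the coefficient of determination
over its hidden entries:

    R²_g = 1 − Σ (x − x̂)² / Σ (x − x̄_g)²,

where x̄_g is the mean of the true evaluated values of gene g. R² ranges from
−∞ to 1; 0 is the score of predicting the per-gene mean, so on standardized
data median imputation sits at ≈ 0 and per-donor surrogate-tissue transfer
can go well below it. Masks are derived deterministically from the seed list,
so different methods evaluated with the same seeds face identical masks
(paired design).

Two scenarios are supported. *Inductive*: fit on a fully observed training
partition, impute an independent masked test partition; the model is trained
once and evaluation masks are redrawn per repetition. *In-place*: the masked
dataset is all there is; trainable methods are re-trained per repetition on
the visible entries themselves (with a donor-aware internal split for early
stopping) and then fill their own gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines as bl
from .datamodel import Mask, MaskedDataset, split_indices
from .gain import GainConfig, gain_impute, train_gain
from .pmi import PMIConfig, pmi_impute, train_pmi
from .synthdata import SynthTruth, oracle_impute

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-gene R²
# ---------------------------------------------------------------------------


def r2_per_gene(
    truth: np.ndarray, imputed: np.ndarray, eval_mask: np.ndarray
) -> np.ndarray:
    """Coefficient of determination per gene over the hidden-and-imputed entries.

    ``eval_mask`` is 1 at entries that were hidden from the imputer and are
    being scored. Genes with fewer than two evaluated entries, or zero
    variance among them, are excluded (NaN) and counted in the log.
    """
    truth = np.asarray(truth, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    ev = np.asarray(eval_mask).astype(bool)
    if not ev.any():
        raise ValueError("evaluation mask selects no entries")
    n_genes = truth.shape[1]
    r2 = np.full(n_genes, np.nan)
    counts = ev.sum(axis=0)
    excluded = 0
    for g in np.flatnonzero(counts >= 2):
        rows = ev[:, g]
        t = truth[rows, g]
        sst = ((t - t.mean()) ** 2).sum()
        if sst <= 0:
            excluded += 1
            continue
        sse = ((t - imputed[rows, g]) ** 2).sum()
        r2[g] = 1.0 - sse / sst
    excluded += int((counts < 2).sum())
    if excluded:
        logger.info("excluded %d gene(s) with <2 evaluated entries or zero variance", excluded)
    return r2


# ---------------------------------------------------------------------------
# Method wrappers (uniform fit/impute surface over all imputers)
# ---------------------------------------------------------------------------


class MedianImputer:
    """Per-(tissue, gene) median of the fit data."""

    name = "median"
    trainable = False

    def __init__(self, tissue_covariate: str = "tissue"):
        self.tissue_covariate = tissue_covariate
        self.medians: bl.MedianTable | None = None

    def fit(self, train: MaskedDataset, val: MaskedDataset | None = None):
        self.medians = bl.fit_medians(train, self.tissue_covariate)
        return self

    def impute(self, data: MaskedDataset, rng=None) -> np.ndarray:
        return bl.median_impute(data, self.medians, self.tissue_covariate).values


class SurrogateImputer:
    """Same-donor surrogate-tissue transfer (e.g. whole blood)."""

    name = "surrogate"
    trainable = False

    def __init__(self, surrogate_label: str = "blood", tissue_covariate: str = "tissue"):
        self.surrogate_label = surrogate_label
        self.tissue_covariate = tissue_covariate
        self.medians: bl.MedianTable | None = None

    def fit(self, train: MaskedDataset, val: MaskedDataset | None = None):
        self.medians = bl.fit_medians(train, self.tissue_covariate)
        return self

    def impute(self, data: MaskedDataset, rng=None) -> np.ndarray:
        return bl.surrogate_impute(
            data, self.surrogate_label, self.tissue_covariate, self.medians
        ).values


class KNNImputer:
    """k-nearest-neighbour imputation against the fit data."""

    trainable = False

    def __init__(self, k: int = 5, tissue_covariate: str = "tissue"):
        self.k = k
        self.name = f"knn{k}"
        self.tissue_covariate = tissue_covariate
        self.reference: MaskedDataset | None = None
        self.medians: bl.MedianTable | None = None

    def fit(self, train: MaskedDataset, val: MaskedDataset | None = None):
        self.reference = train
        self.medians = bl.fit_medians(train, self.tissue_covariate)
        return self

    def impute(self, data: MaskedDataset, rng=None) -> np.ndarray:
        return bl.knn_impute(
            data, self.k, self.reference, self.medians, self.tissue_covariate
        ).values


class PMIImputer:
    name = "pmi"
    trainable = True

    def __init__(self, config: PMIConfig | None = None):
        self.config = config or PMIConfig()
        self.model = None
        self.log = None

    def fit(self, train: MaskedDataset, val: MaskedDataset | None = None):
        self.model, self.log = train_pmi(train, val if val is not None else train, self.config)
        return self

    def impute(self, data: MaskedDataset, rng=None) -> np.ndarray:
        return pmi_impute(data, self.model).values


class GainImputer:
    trainable = True

    def __init__(self, config: GainConfig | None = None, n_draws: int = 1):
        self.config = config or GainConfig()
        self.name = "gain" if self.config.adversarial else "gain_mse"
        self.n_draws = n_draws
        self.model = None
        self.log = None

    def fit(self, train: MaskedDataset, val: MaskedDataset | None = None):
        self.model, self.log = train_gain(train, val if val is not None else train, self.config)
        return self

    def impute(self, data: MaskedDataset, rng=None) -> np.ndarray:
        rng = rng or np.random.default_rng(self.config.seed + 40_009)
        return gain_impute(data, self.model, rng, self.n_draws).values


class OracleImputer:
    """Closed-form Gaussian conditional-mean ceiling (synthetic data only)."""

    name = "oracle"
    trainable = False

    def __init__(self, truth: SynthTruth, tissue_covariate: str = "tissue"):
        self.truth = truth
        self.tissue_covariate = tissue_covariate

    def fit(self, train: MaskedDataset, val: MaskedDataset | None = None):
        return self

    def impute(self, data: MaskedDataset, rng=None) -> np.ndarray:
        tissues = data.covariates.column(self.tissue_covariate)
        sex = np.where(data.covariates.column("sex") == 2, 1.0, -1.0)
        age = data.covariates.numeric[:, data.covariates.numeric_names.index("age")]
        x = data.observed_values()
        out = np.empty_like(x)
        for i in range(data.n_samples):
            out[i] = oracle_impute(
                x[i],
                data.mask.values[i],
                int(tissues[i]),
                self.truth.oracle,
                float(age[i]),
                float(sex[i]),
            )
        return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-gene R² across repetitions, with the aggregates the protocol reports."""

    method: str
    scenario: str
    missing_rate: float
    seeds: list[int]
    gene_ids: list[str]
    per_gene_r2: np.ndarray  # (repetitions, genes), NaN for excluded genes
    truth: np.ndarray | None = None  # (samples, genes)
    imputed: list[np.ndarray] = field(default_factory=list)
    eval_masks: list[np.ndarray] = field(default_factory=list)
    sample_ids: list[str] | None = None

    @property
    def per_gene_mean(self) -> np.ndarray:
        return np.nanmean(self.per_gene_r2, axis=0)

    @property
    def overall_mean_r2(self) -> float:
        """Mean over genes of the mean over repetitions."""
        return float(np.nanmean(self.per_gene_mean))

    @property
    def mean_per_gene_sd(self) -> float:
        """Per-gene SD of R² across repetitions, averaged over genes."""
        with np.errstate(all="ignore"):
            sd = np.nanstd(self.per_gene_r2, axis=0)
        return float(np.nanmean(sd))

    def summary(self) -> dict:
        return {
            "method": self.method,
            "scenario": self.scenario,
            "missing_rate": self.missing_rate,
            "repetitions": int(self.per_gene_r2.shape[0]),
            "seeds": list(map(int, self.seeds)),
            "overall_mean_r2": self.overall_mean_r2,
            "mean_per_gene_sd": self.mean_per_gene_sd,
            "n_genes_scored": int(np.isfinite(self.per_gene_mean).sum()),
        }

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.per_gene_r2.T,
            index=self.gene_ids,
            columns=[f"rep{k}" for k in range(self.per_gene_r2.shape[0])],
        )
        df.index.name = "gene_id"
        return df


def _masked_view(data: MaskedDataset, visible: np.ndarray) -> MaskedDataset:
    """Copy of ``data`` with only ``visible`` entries observed; hidden entries
    are poisoned with NaN so illegal reads propagate loudly."""
    x = data.expression.values.copy()
    x[visible == 0] = np.nan
    expr = type(data.expression)(
        x,
        data.expression.gene_ids,
        data.expression.sample_ids,
        data.expression.donor_ids,
        data.expression.standardized,
        data.expression.gene_means,
        data.expression.gene_sds,
    )
    return MaskedDataset(expr, Mask(visible), data.covariates)


def _eval_mask_for(seed: int, shape: tuple[int, int], rate: float, base_mask: np.ndarray):
    """Deterministic MCAR evaluation mask over the observed entries."""
    rng = np.random.default_rng(seed)
    keep = (rng.random(shape) >= rate).astype(np.int8)
    visible = (base_mask * keep).astype(np.int8)
    hidden = (base_mask * (1 - keep)).astype(np.int8)
    return visible, hidden


def run_scenario(
    scenario: str,
    data: MaskedDataset,
    imputer,
    missing_rate: float = 0.5,
    repetitions: int = 3,
    seeds: list[int] | None = None,
    train: MaskedDataset | None = None,
    val: MaskedDataset | None = None,
    keep_arrays: bool = True,
) -> EvalReport:
    """Run one method through the repetition protocol of a scenario.

    ``data`` is the dataset whose entries are hidden and scored (the test
    partition in inductive mode). Inductive additionally requires ``train``
    (and optionally ``val``) and fits once; in-place re-fits per repetition on
    the masked data itself. Seeds default to ``range(repetitions)``.
    """
    if scenario not in ("inductive", "in_place"):
        raise ValueError(f"unknown scenario {scenario!r}")
    seeds = list(seeds) if seeds is not None else list(range(repetitions))
    if len(seeds) != repetitions:
        raise ValueError("need one seed per repetition")
    if scenario == "inductive":
        if train is None:
            raise ValueError("inductive scenario requires a training set")
        imputer.fit(train, val)

    truth = data.expression.values
    shape = truth.shape
    scores, imputed_list, hidden_list = [], [], []
    for rep, seed in enumerate(seeds):
        visible, hidden = _eval_mask_for(seed, shape, missing_rate, data.mask.values)
        masked = _masked_view(data, visible)
        if scenario == "in_place":
            if imputer.trainable:
                tr_idx, va_idx, te_idx = split_indices(
                    masked.expression.donor_ids, (0.7, 0.15, 0.15)
                )
                fit_part = masked.subset_rows(np.sort(np.concatenate([tr_idx, te_idx])))
                imputer.fit(fit_part, masked.subset_rows(va_idx))
            else:
                imputer.fit(masked)
        x_hat = imputer.impute(masked, np.random.default_rng(seed + 70_001))
        assert np.isfinite(x_hat[hidden == 1]).all(), "imputer produced non-finite values"
        scores.append(r2_per_gene(truth, x_hat, hidden))
        if keep_arrays:
            imputed_list.append(x_hat)
            hidden_list.append(hidden)
    return EvalReport(
        method=imputer.name,
        scenario=scenario,
        missing_rate=missing_rate,
        seeds=seeds,
        gene_ids=list(data.expression.gene_ids),
        per_gene_r2=np.vstack(scores),
        truth=truth if keep_arrays else None,
        imputed=imputed_list,
        eval_masks=hidden_list,
        sample_ids=list(data.expression.sample_ids) if keep_arrays else None,
    )


def missing_rate_sweep(
    data: MaskedDataset,
    imputer,
    rates: list[float],
    repetitions: int = 3,
    seeds: list[int] | None = None,
    train: MaskedDataset | None = None,
    val: MaskedDataset | None = None,
) -> list[EvalReport]:
    """Evaluate one fixed trained model across missing rates.

    The model is fitted once (on ``train`` if given, else assumed already
    fitted) and then scored at each rate with deterministic per-(rate,
    repetition) masks, so different methods swept with the same seeds face
    identical masks. Returns one report per rate.
    """
    if sorted(rates) != list(rates) or any(not 0 < r < 1 for r in rates):
        raise ValueError("rates must be sorted and inside (0, 1)")
    seeds = list(seeds) if seeds is not None else list(range(repetitions))
    if train is not None:
        imputer.fit(train, val)

    truth = data.expression.values
    reports = []
    for rate in rates:
        scores = []
        rate_seeds = [int(s * 1009 + round(rate * 1000)) % (2**31 - 1) for s in seeds]
        for seed in rate_seeds:
            visible, hidden = _eval_mask_for(seed, truth.shape, rate, data.mask.values)
            x_hat = imputer.impute(_masked_view(data, visible), np.random.default_rng(seed + 70_001))
            scores.append(r2_per_gene(truth, x_hat, hidden))
        reports.append(
            EvalReport(
                method=imputer.name,
                scenario="inductive" if train is not None else "in_place",
                missing_rate=rate,
                seeds=rate_seeds,
                gene_ids=list(data.expression.gene_ids),
                per_gene_r2=np.vstack(scores),
            )
        )
    return reports


def aggregate_by_group(report: EvalReport, grouping: np.ndarray) -> pd.DataFrame:
    """Per-group per-gene R² distributions (e.g. per tissue).

    ``grouping`` assigns one label per sample of the report. Scores are
    recomputed within each group's samples from the stored truth/imputed
    arrays; the summary gives mean and quartiles of each group's per-gene R²
    distribution (genes with <2 evaluated entries in a group are skipped).
    """
    if report.truth is None or not report.imputed:
        raise ValueError("report was created with keep_arrays=False")
    grouping = np.asarray(grouping)
    if grouping.shape[0] != report.truth.shape[0]:
        raise ValueError("grouping must cover all samples")
    rows = []
    for group in pd.unique(grouping):
        idx = grouping == group
        per_rep = [
            r2_per_gene(report.truth[idx], xh[idx], ev[idx])
            for xh, ev in zip(report.imputed, report.eval_masks)
        ]
        mean_scores = np.nanmean(np.vstack(per_rep), axis=0)
        valid = mean_scores[np.isfinite(mean_scores)]
        q1, q2, q3 = np.percentile(valid, [25, 50, 75]) if valid.size else (np.nan,) * 3
        rows.append(
            {
                "group": group,
                "n_samples": int(idx.sum()),
                "n_genes_scored": int(valid.size),
                "mean_r2": float(valid.mean()) if valid.size else np.nan,
                "q1": q1,
                "median": q2,
                "q3": q3,
                "iqr": q3 - q1,
            }
        )
    return pd.DataFrame(rows).set_index("group")
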