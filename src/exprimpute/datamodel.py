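"""Core data containers, standardization, donor-aware splitting, and file I/O.

Expression data live in a samples × genes real matrix. Missingness is carried
separately as a binary observation mask (1 = observed), so the raw values at
missing positions are never meaningful and may be NaN. Covariates are split
into categorical columns (integer codes ``1..v_j`` with label maps) and
numeric columns (standardized to zero mean, unit SD on the training rows).

Standardization is per gene (standard score) and is always *fitted* on the
training partition only, then applied everywhere, so that test statistics can
never leak into the model. Donor-aware splitting guarantees that all samples
from one donor land in the same partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ddof used for the per-gene standard score (population SD).
STANDARDIZE_DDOF = 0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A samples × genes real-valued expression matrix with identifiers.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_samples, n_genes)``.
    gene_ids, sample_ids, donor_ids
        Column / row identifiers; ``donor_ids`` has one entry per sample and
        may repeat (several samples of the same donor across tissues).
    standardized
        Whether ``values`` are in per-gene standard-score units.
    gene_means, gene_sds
        The fitted standardization parameters (present iff standardized, or
        kept for the inverse transform).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    donor_ids: list[str]
    standardized: bool = False
    gene_means: np.ndarray | None = None
    gene_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        s, n = self.values.shape
        if len(self.sample_ids) != s or len(self.donor_ids) != s:
            raise ValueError(
                f"row count {s} != sample_ids ({len(self.sample_ids)}) "
                f"or donor_ids ({len(self.donor_ids)})"
            )
        if len(self.gene_ids) != n:
            raise ValueError(f"column count {n} != gene_ids ({len(self.gene_ids)})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            donor_ids=[self.donor_ids[i] for i in idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            gene_means=None if self.gene_means is None else self.gene_means[idx],
            gene_sds=None if self.gene_sds is None else self.gene_sds[idx],
        )


@dataclass
class Mask:
    """Binary observation matrix: 1 = observed, 0 = missing."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        self.values = v.astype(np.int8)

    @property
    def observed_fraction(self) -> float:
        return float(self.values.mean())

    def subset_rows(self, idx: np.ndarray) -> "Mask":
        return Mask(self.values[np.asarray(idx)])

    def subset_genes(self, idx: np.ndarray) -> "Mask":
        return Mask(self.values[:, np.asarray(idx)])


@dataclass
class CovariateTable:
    """Per-sample covariates: integer-coded categoricals plus numerics.

    Categorical codes are 1-based (``q_j ∈ {1, …, v_j}``); ``vocab[j]`` maps
    code − 1 to the original label. Numeric covariates are stored standardized
    (mean 0, SD 1 fitted on training rows) with the fit parameters retained.
    """

    categorical_names: list[str]
    codes: np.ndarray  # (n_samples, c), int, 1-based
    vocab: list[list[str]]  # per covariate: label for code k is vocab[j][k-1]
    numeric_names: list[str] = field(default_factory=list)
    numeric: np.ndarray | None = None  # (n_samples, k), standardized
    numeric_means: np.ndarray | None = None
    numeric_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.categorical_names):
            raise ValueError("codes must be (n_samples, n_categorical)")
        for j, name in enumerate(self.categorical_names):
            v = len(self.vocab[j])
            col = self.codes[:, j]
            if col.min(initial=1) < 1 or col.max(initial=1) > v:
                raise ValueError(
                    f"categorical covariate {name!r}: codes must lie in 1..{v}"
                )
        if self.numeric is None:
            self.numeric = np.zeros((self.codes.shape[0], 0))
        self.numeric = np.asarray(self.numeric, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def vocab_sizes(self) -> list[int]:
        return [len(v) for v in self.vocab]

    @property
    def n_numeric(self) -> int:
        return self.numeric.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return 1-based codes of a categorical covariate by name."""
        return self.codes[:, self.categorical_names.index(name)]

    def labels(self, name: str) -> np.ndarray:
        j = self.categorical_names.index(name)
        return np.asarray(self.vocab[j], dtype=object)[self.codes[:, j] - 1]

    def subset_rows(self, idx: np.ndarray) -> "CovariateTable":
        idx = np.asarray(idx)
        return replace(self, codes=self.codes[idx], numeric=self.numeric[idx])

    def standardize_numeric(self, fit_rows: np.ndarray) -> "CovariateTable":
        """Standard-score the numeric covariates, fitted on ``fit_rows``."""
        if self.n_numeric == 0:
            return self
        sub = self.numeric[np.asarray(fit_rows)]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=STANDARDIZE_DDOF)
        sd = np.where(sd > 0, sd, 1.0)
        return replace(
            self, numeric=(self.numeric - mu) / sd, numeric_means=mu, numeric_sds=sd
        )


@dataclass
class MaskedDataset:
    """The unit every imputer consumes: expression + mask + covariates.

    Values at ``mask == 0`` positions are undefined and must never be read;
    tests poison them with NaN to enforce this.
    """

    expression: ExpressionMatrix
    mask: Mask
    covariates: CovariateTable

    def __post_init__(self) -> None:
        if self.mask.values.shape != self.expression.values.shape:
            raise ValueError("mask shape must match expression shape")
        if self.covariates.n_samples != self.expression.n_samples:
            raise ValueError("covariate rows must match expression rows")

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def n_genes(self) -> int:
        return self.expression.n_genes

    def observed_values(self) -> np.ndarray:
        """Expression with missing entries zeroed (x ⊙ m)."""
        return np.where(self.mask.values == 1, self.expression.values, 0.0)

    def subset_rows(self, idx: np.ndarray) -> "MaskedDataset":
        return MaskedDataset(
            self.expression.subset_rows(idx),
            self.mask.subset_rows(idx),
            self.covariates.subset_rows(idx),
        )

    def subset_genes(self, idx: np.ndarray) -> "MaskedDataset":
        return MaskedDataset(
            self.expression.subset_genes(idx), self.mask.subset_genes(idx), self.covariates
        )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize(
    expr: ExpressionMatrix,
    mask: Mask,
    fit_rows: np.ndarray,
    *,
    on_degenerate: str = "drop",
) -> ExpressionMatrix:
    """Per-gene standard score, fitted on the observed entries of ``fit_rows``.

    Mean and SD (population SD, ``ddof=0``) are computed per gene over the
    entries of the training rows where the mask is 1, then applied to all
    rows. Genes with fewer than two observed training values or zero variance
    are degenerate (the standard score is undefined); they are dropped with a
    warning (``on_degenerate="drop"``) or raise (``"error"``).
    """
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be nonempty")
    x = expr.values[fit_rows]
    m = mask.values[fit_rows].astype(bool)
    counts = m.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.where(counts > 0, np.nansum(np.where(m, x, np.nan), axis=0), np.nan)
    means = np.divide(means, counts, out=np.full(expr.n_genes, np.nan), where=counts > 0)
    centered = np.where(m, x - means, 0.0)
    var = np.divide(
        (centered**2).sum(axis=0),
        counts,
        out=np.zeros(expr.n_genes),
        where=counts > 0,
    )
    sds = np.sqrt(var)

    degenerate = (counts < 2) | (sds <= 0)
    if degenerate.any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(degenerate)]
        msg = f"{len(bad)} gene(s) with <2 observations or zero variance: {bad[:10]}"
        if on_degenerate == "error":
            raise ValueError(msg)
        warnings.warn(f"dropping degenerate genes — {msg}", stacklevel=2)
        logger.warning("dropping degenerate genes: %s", bad)
        keep = np.flatnonzero(~degenerate)
        expr = expr.subset_genes(keep)
        means, sds = means[keep], sds[keep]

    out = (expr.values - means) / sds
    return replace(
        expr, values=out, standardized=True, gene_means=means, gene_sds=sds
    )


def destandardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Invert the per-gene standard score using the stored parameters."""
    if not expr.standardized:
        raise ValueError("matrix is not standardized")
    if expr.gene_means is None or expr.gene_sds is None:
        raise ValueError("standardization parameters missing")
    out = expr.values * expr.gene_sds + expr.gene_means
    return replace(expr, values=out, standardized=False)


def standardize_dataset(
    data: MaskedDataset, fit_rows: np.ndarray, *, on_degenerate: str = "drop"
) -> MaskedDataset:
    """Standardize expression and numeric covariates, fitted on ``fit_rows``.

    Degenerate genes dropped by :func:`standardize` are removed from the mask
    as well, keeping the dataset consistent.
    """
    expr = standardize(data.expression, data.mask, fit_rows, on_degenerate=on_degenerate)
    mask = data.mask
    if expr.n_genes != data.expression.n_genes:
        pos = {g: i for i, g in enumerate(data.expression.gene_ids)}
        mask = mask.subset_genes(np.array([pos[g] for g in expr.gene_ids]))
    cov = data.covariates.standardize_numeric(fit_rows)
    return MaskedDataset(expr, mask, cov)


# ---------------------------------------------------------------------------
# Donor-aware splitting
# ---------------------------------------------------------------------------


def flip_donor_id(donor_id: str) -> str:
    """Reverse a donor identifier character-wise (e.g. 111CU-1826 → 6281-UC111).

    Reversing before sorting scrambles any enrolment-order or site structure
    encoded in identifier prefixes, making the alphabetical split effectively
    arbitrary yet fully deterministic.
    """
    if not donor_id:
        raise ValueError("donor_id must be nonempty")
    return donor_id[::-1]


def donor_split(
    donor_ids: list[str], fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> tuple[set[str], set[str], set[str]]:
    """Deterministic donor-level train/validation/test split.

    All samples of a donor stay together. Donors are ordered by their flipped
    identifier alphabetically; cut points are chosen so the realized
    cumulative *sample* fractions are as close as possible to the requested
    ones (each partition gets at least one donor).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts: dict[str, int] = {}
    for d in donor_ids:
        counts[d] = counts.get(d, 0) + 1
    donors = sorted(counts, key=flip_donor_id)
    n_d = len(donors)
    if n_d < 3:
        raise ValueError(f"need at least 3 distinct donors, got {n_d}")
    weights = np.array([counts[d] for d in donors], dtype=float)
    cum = np.cumsum(weights) / weights.sum()  # cum[i] = fraction after donor i

    # cut1 donors go to train, donors cut1..cut2-1 to val, rest to test
    t1 = fractions[0]
    t2 = fractions[0] + fractions[1]
    c1_candidates = np.arange(1, n_d - 1)  # leave ≥1 donor for val and test
    cut1 = int(c1_candidates[np.argmin(np.abs(cum[c1_candidates - 1] - t1))])
    c2_candidates = np.arange(cut1 + 1, n_d)
    cut2 = int(c2_candidates[np.argmin(np.abs(cum[c2_candidates - 1] - t2))])

    return set(donors[:cut1]), set(donors[cut1:cut2]), set(donors[cut2:])


def split_indices(
    donor_ids: list[str], fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row indices of the donor-aware train/val/test partitions."""
    train_d, val_d, test_d = donor_split(donor_ids, fractions)
    ids = np.asarray(donor_ids, dtype=object)
    return (
        np.flatnonzero([d in train_d for d in ids]),
        np.flatnonzero([d in val_d for d in ids]),
        np.flatnonzero([d in test_d for d in ids]),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_expression(
    path,
    dialect: str | None = None,
    *,
    transpose: bool = False,
    donor_from_sample=None,
) -> tuple[ExpressionMatrix, Mask]:
    """Read a delimited expression table into a matrix + observation mask.

    The header row holds gene ids and the first column sample ids (swap with
    ``transpose=True`` for genes-as-rows files). Empty cells and NaN become
    mask = 0. ``donor_from_sample`` optionally maps a sample id to its donor
    id (default: the part before the last underscore, else the sample id).
    """
    sep = _sep_for(path, dialect)
    # pandas silently renames duplicate column labels; check the raw header
    header = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0].tolist()[1:]
    # round-trip parsing keeps write→read→write cycles bit-identical
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    if transpose:  # raw columns are samples, raw rows are genes
        sample_labels, gene_labels = header, df.columns.tolist()
    else:
        sample_labels, gene_labels = df.index.tolist(), header
    for labels, what in ((sample_labels, "sample id"), (gene_labels, "gene id")):
        seen: set = set()
        dup = sorted({x for x in labels if x in seen or seen.add(x)})
        if dup:
            raise ValueError(f"duplicate {what}(s) in {path}: {dup}")
    values = df.to_numpy(dtype=float)
    mask = Mask((~np.isnan(values)).astype(np.int8))
    sample_ids = [str(s) for s in df.index]
    if donor_from_sample is None:
        donor_from_sample = lambda s: s.rsplit("_", 1)[0] if "_" in s else s
    donor_ids = [donor_from_sample(s) for s in sample_ids]
    expr = ExpressionMatrix(
        np.nan_to_num(values), [str(g) for g in df.columns], sample_ids, donor_ids
    )
    return expr, mask


def write_expression(
    expr: ExpressionMatrix, mask: Mask | None, path, dialect: str | None = None
) -> None:
    """Write an expression matrix; entries at mask == 0 are left empty (NaN)."""
    values = expr.values.astype(float).copy()
    if mask is not None:
        values[mask.values == 0] = np.nan
    df = pd.DataFrame(values, index=expr.sample_ids, columns=expr.gene_ids)
    df.to_csv(path, sep=_sep_for(path, dialect))


def read_covariates(path, schema: dict, dialect: str | None = None) -> pd.DataFrame:
    """Read a covariate table keyed by sample id; schema declares column types.

    ``schema`` is ``{"categorical": {name: vocabulary-or-None}, "numeric": [...]}``.
    Returns the raw DataFrame; use :func:`covariates_from_frame` to code it.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    missing = [
        c
        for c in list(schema.get("categorical", {})) + list(schema.get("numeric", []))
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"covariate column(s) missing from {path}: {missing}")
    return df


def covariates_from_frame(
    df: pd.DataFrame, schema: dict, sample_ids: list[str]
) -> CovariateTable:
    """Integer-code the categorical columns of a covariate frame.

    The vocabulary is taken from the schema when given (order preserved),
    otherwise from the sorted unique values in the data.
    """
    df = df.loc[sample_ids]
    cat_schema = schema.get("categorical", {})
    names, codes_cols, vocab = [], [], []
    for name, voc in cat_schema.items():
        col = df[name].astype(str)
        voc = [str(v) for v in voc] if voc else sorted(col.unique())
        lut = {label: k + 1 for k, label in enumerate(voc)}
        unknown = sorted(set(col) - set(lut))
        if unknown:
            raise ValueError(f"covariate {name!r}: labels outside vocabulary: {unknown}")
        names.append(name)
        codes_cols.append(col.map(lut).to_numpy())
        vocab.append(voc)
    codes = (
        np.stack(codes_cols, axis=1) if codes_cols else np.zeros((len(df), 0), dtype=int)
    )
    num_names = list(schema.get("numeric", []))
    numeric = df[num_names].to_numpy(dtype=float) if num_names else None
    return CovariateTable(names, codes, vocab, num_names, numeric)
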