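"""Containers, standardization, donor-aware splitting, and file I/O."""

from __future__ import annotations

import numpy as np
import pytest

from exprimpute.datamodel import (
    CovariateTable,
    ExpressionMatrix,
    Mask,
    MaskedDataset,
    covariates_from_frame,
    destandardize,
    donor_split,
    flip_donor_id,
    read_covariates,
    read_expression,
    split_indices,
    standardize,
    standardize_dataset,
    write_expression,
)

from .conftest import make_dataset


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def test_expression_matrix_validates_shapes():
    with pytest.raises(ValueError, match="2-D"):
        ExpressionMatrix(np.zeros(3), ["g"], ["s"], ["d"])
    with pytest.raises(ValueError, match="row count"):
        ExpressionMatrix(np.zeros((2, 1)), ["g"], ["s"], ["d"])
    with pytest.raises(ValueError, match="column count"):
        ExpressionMatrix(np.zeros((1, 2)), ["g"], ["s"], ["d"])


def test_mask_rejects_non_binary():
    with pytest.raises(ValueError, match="0 or 1"):
        Mask(np.array([[0, 2]]))


def test_subset_rows_and_genes_consistent():
    data = make_dataset(np.arange(12.0).reshape(3, 4), np.ones((3, 4)), [1, 2, 3])
    sub = data.subset_rows(np.array([2, 0]))
    assert sub.expression.values.tolist() == [[8, 9, 10, 11], [0, 1, 2, 3]]
    assert sub.expression.sample_ids == [data.expression.sample_ids[i] for i in (2, 0)]
    assert sub.covariates.codes[:, 0].tolist() == [3, 1]
    subg = data.subset_genes(np.array([1, 3]))
    assert subg.expression.gene_ids == ["G1", "G3"]
    assert subg.expression.values.tolist() == [[1, 3], [5, 7], [9, 11]]


def test_masked_dataset_validates_alignment():
    expr = ExpressionMatrix(np.zeros((2, 2)), ["a", "b"], ["s1", "s2"], ["d1", "d2"])
    cov = CovariateTable(["t"], np.ones((2, 1), dtype=int), [["x"]])
    with pytest.raises(ValueError, match="mask shape"):
        MaskedDataset(expr, Mask(np.ones((3, 2))), cov)
    with pytest.raises(ValueError, match="covariate rows"):
        MaskedDataset(expr, Mask(np.ones((2, 2))), cov.subset_rows(np.array([0])))


def test_observed_values_zeroes_missing():
    data = make_dataset([[1.0, np.nan], [3.0, 4.0]], [[1, 0], [1, 1]], [1, 2])
    assert data.observed_values().tolist() == [[1.0, 0.0], [3.0, 4.0]]


def test_covariate_table_codes_are_one_based():
    with pytest.raises(ValueError, match="1..2"):
        CovariateTable(["t"], np.array([[0]]), [["a", "b"]])
    with pytest.raises(ValueError, match="1..2"):
        CovariateTable(["t"], np.array([[3]]), [["a", "b"]])
    cov = CovariateTable(["t"], np.array([[2], [1]]), [["a", "b"]])
    assert cov.labels("t").tolist() == ["b", "a"]
    assert cov.vocab_sizes == [2]


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def test_standardize_matches_brute_force():
    rng = np.random.default_rng(5)
    x = rng.normal(2.0, 3.0, size=(30, 6))
    m = (rng.random((30, 6)) > 0.3).astype(int)
    expr = ExpressionMatrix(x, [f"g{i}" for i in range(6)], [f"s{i}" for i in range(30)], [f"d{i}" for i in range(30)])
    fit_rows = np.arange(20)
    out = standardize(expr, Mask(m), fit_rows)
    # brute force per gene over observed fit entries
    for g in range(6):
        obs = m[:20, g] == 1
        mu = x[:20, g][obs].mean()
        sd = x[:20, g][obs].std(ddof=0)
        np.testing.assert_allclose(out.gene_means[g], mu, rtol=1e-12)
        np.testing.assert_allclose(out.gene_sds[g], sd, rtol=1e-12)
        np.testing.assert_allclose(out.values[:, g], (x[:, g] - mu) / sd, rtol=1e-12)
    # observed fit entries have mean 0, SD 1 after the transform
    for g in range(6):
        obs = m[:20, g] == 1
        v = out.values[:20, g][obs]
        assert abs(v.mean()) < 1e-12
        np.testing.assert_allclose(v.std(ddof=0), 1.0, rtol=1e-12)


def test_standardize_ignores_values_at_missing_positions():
    x = np.array([[1.0, 5.0], [3.0, 6.0], [np.nan, 7.0]])
    m = np.array([[1, 1], [1, 1], [0, 1]])
    expr = ExpressionMatrix(x, ["a", "b"], ["s1", "s2", "s3"], ["d1", "d2", "d3"])
    out = standardize(expr, Mask(m), np.arange(3))
    np.testing.assert_allclose(out.gene_means, [2.0, 6.0])
    assert np.isfinite(out.values[:, 1]).all()


def test_standardize_drops_degenerate_genes_with_warning():
    x = np.array([[1.0, 5.0, 2.0], [3.0, 5.0, 2.0], [2.0, 5.0, 2.0]])
    m = np.array([[1, 1, 1], [1, 1, 0], [1, 1, 0]])  # gene1 zero variance, gene2 <2 obs
    expr = ExpressionMatrix(x, ["a", "b", "c"], ["s1", "s2", "s3"], ["d1", "d2", "d3"])
    with pytest.warns(UserWarning, match="degenerate"):
        out = standardize(expr, Mask(m), np.arange(3))
    assert out.gene_ids == ["a"]
    with pytest.raises(ValueError, match="zero variance"):
        standardize(expr, Mask(m), np.arange(3), on_degenerate="error")


def test_standardize_requires_fit_rows():
    expr = ExpressionMatrix(np.ones((2, 1)), ["a"], ["s1", "s2"], ["d1", "d2"])
    with pytest.raises(ValueError, match="nonempty"):
        standardize(expr, Mask(np.ones((2, 1))), np.array([], dtype=int))


def test_destandardize_round_trip():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(10, 4)) * 5 + 3
    expr = ExpressionMatrix(x, [f"g{i}" for i in range(4)], [f"s{i}" for i in range(10)], [f"d{i}" for i in range(10)])
    std = standardize(expr, Mask(np.ones((10, 4))), np.arange(10))
    back = destandardize(std)
    np.testing.assert_allclose(back.values, x, rtol=1e-12)
    assert not back.standardized
    with pytest.raises(ValueError, match="not standardized"):
        destandardize(expr)


def test_standardize_dataset_drops_mask_columns_too():
    data = make_dataset(
        [[1.0, 5.0], [3.0, 5.0], [2.0, 5.0]], np.ones((3, 2)), [1, 2, 3],
        age=np.array([10.0, 20.0, 30.0]),
    )
    with pytest.warns(UserWarning):
        out = standardize_dataset(data, np.arange(3))
    assert out.n_genes == 1
    assert out.mask.values.shape == (3, 1)
    # numeric covariates standardized on the fit rows
    np.testing.assert_allclose(out.covariates.numeric.mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.covariates.numeric.std(ddof=0), 1.0, rtol=1e-12)


# ---------------------------------------------------------------------------
# Donor-aware splitting
# ---------------------------------------------------------------------------


def test_flip_donor_id_example():
    assert flip_donor_id("111CU-1826") == "6281-UC111"
    with pytest.raises(ValueError):
        flip_donor_id("")


def test_donor_split_is_donor_disjoint_and_complete():
    rng = np.random.default_rng(11)
    donors = [f"D{rng.integers(0, 40):03d}" for _ in range(200)]
    tr, va, te = donor_split(donors)
    assert tr and va and te
    assert not (tr & va or tr & te or va & te)
    assert tr | va | te == set(donors)


def test_donor_split_realized_fractions_close():
    donors = [f"D{i:04d}" for i in range(500)]
    tr, va, te = donor_split(donors, (0.6, 0.2, 0.2))
    fr = np.array([len(tr), len(va), len(te)]) / 500
    # with 500 equal-weight donors each cut is off by at most one donor
    np.testing.assert_allclose(fr, [0.6, 0.2, 0.2], atol=1 / 500 + 1e-12)


def test_donor_split_orders_by_flipped_id():
    # flipped order: "ab"->"ba", "ba"->"ab", "ca"->"ac" => sorted: ba, ca, ab
    tr, va, te = donor_split(["ab", "ba", "ca"], (1 / 3, 1 / 3, 1 / 3))
    assert (tr, va, te) == ({"ba"}, {"ca"}, {"ab"})


def test_donor_split_validates():
    with pytest.raises(ValueError, match="sum to 1"):
        donor_split(["a", "b", "c"], (0.5, 0.2, 0.2))
    with pytest.raises(ValueError, match="at least 3"):
        donor_split(["a", "a", "b"])


def test_split_indices_covers_all_rows_once():
    donors = ["d1", "d2", "d1", "d3", "d4", "d2", "d5"]
    tr, va, te = split_indices(donors)
    all_idx = np.sort(np.concatenate([tr, va, te]))
    assert all_idx.tolist() == list(range(7))
    for part in (tr, va, te):
        for other in (tr, va, te):
            if part is not other:
                donors_a = {donors[i] for i in part}
                donors_b = {donors[i] for i in other}
                assert not donors_a & donors_b


def test_split_is_deterministic():
    donors = [f"D{i:03d}" for i in range(50)]
    assert donor_split(donors) == donor_split(list(donors))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def test_expression_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    x = rng.normal(size=(5, 3))
    m = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1], [0, 1, 1], [1, 1, 1]])
    expr = ExpressionMatrix(
        x, ["g1", "g2", "g3"], [f"D{i}_t" for i in range(5)], [f"D{i}" for i in range(5)]
    )
    path = tmp_path / "expr.tsv"
    write_expression(expr, Mask(m), path)
    expr2, mask2 = read_expression(path)
    assert mask2.values.tolist() == m.tolist()
    np.testing.assert_allclose(expr2.values[m == 1], x[m == 1], rtol=1e-12)
    assert expr2.gene_ids == expr.gene_ids
    assert expr2.sample_ids == expr.sample_ids
    assert expr2.donor_ids == [f"D{i}" for i in range(5)]  # part before last "_"


def test_read_expression_csv_dialect(tmp_path):
    path = tmp_path / "expr.csv"
    path.write_text("sample,g1,g2\ns1,1.5,\ns2,2.5,3.5\n")
    expr, mask = read_expression(path)
    assert mask.values.tolist() == [[1, 0], [1, 1]]
    assert expr.values[0, 0] == 1.5


def test_read_expression_rejects_duplicates(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("sample\tg1\tg1\ns1\t1\t2\n")
    with pytest.raises(ValueError, match="duplicate gene"):
        read_expression(path)
    path.write_text("sample\tg1\ns1\t1\ns1\t2\n")
    with pytest.raises(ValueError, match="duplicate sample"):
        read_expression(path)


def test_read_covariates_missing_column(tmp_path):
    path = tmp_path / "cov.tsv"
    path.write_text("sample_id\ttissue\ns1\tblood\n")
    schema = {"categorical": {"tissue": None, "sex": None}, "numeric": []}
    with pytest.raises(ValueError, match="sex"):
        read_covariates(path, schema)


def test_covariates_from_frame_codes_and_vocab(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {"tissue": ["lung", "blood", "lung"], "age": [40.0, 50.0, 60.0]},
        index=["s1", "s2", "s3"],
    )
    schema = {"categorical": {"tissue": ["blood", "lung"]}, "numeric": ["age"]}
    cov = covariates_from_frame(df, schema, ["s2", "s1", "s3"])
    assert cov.codes[:, 0].tolist() == [1, 2, 2]  # vocabulary order preserved
    assert cov.numeric[:, 0].tolist() == [50.0, 40.0, 60.0]
    bad = {"categorical": {"tissue": ["blood"]}, "numeric": []}
    with pytest.raises(ValueError, match="outside vocabulary"):
        covariates_from_frame(df, bad, ["s1", "s2", "s3"])
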