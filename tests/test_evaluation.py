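"""Per-gene R², scenario protocol, pairing, poisoning, and sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from exprimpute.evaluation import (
    EvalReport,
    KNNImputer,
    MedianImputer,
    OracleImputer,
    _eval_mask_for,
    _masked_view,
    aggregate_by_group,
    missing_rate_sweep,
    r2_per_gene,
    run_scenario,
)
from exprimpute.synthdata import SynthConfig, generate_dataset

from .conftest import make_dataset


# ---------------------------------------------------------------------------
# r2_per_gene closed forms
# ---------------------------------------------------------------------------


def test_r2_perfect_prediction_is_one(rng):
    truth = rng.normal(size=(20, 4))
    ev = (rng.random((20, 4)) > 0.4).astype(np.int8)
    np.testing.assert_allclose(r2_per_gene(truth, truth.copy(), ev), np.ones(4))


def test_r2_mean_prediction_is_zero(rng):
    truth = rng.normal(size=(30, 3))
    ev = (rng.random((30, 3)) > 0.3).astype(np.int8)
    pred = truth.copy()
    for g in range(3):
        pred[ev[:, g] == 1, g] = truth[ev[:, g] == 1, g].mean()
    np.testing.assert_allclose(r2_per_gene(truth, pred, ev), np.zeros(3), atol=1e-12)


def test_r2_constant_offset_closed_form(rng):
    truth = rng.normal(size=(50, 2))
    ev = np.ones((50, 2), dtype=np.int8)
    c = 0.7
    got = r2_per_gene(truth, truth + c, ev)
    for g in range(2):
        sst = ((truth[:, g] - truth[:, g].mean()) ** 2).sum()
        np.testing.assert_allclose(got[g], 1.0 - 50 * c**2 / sst, rtol=1e-12)


def test_r2_excludes_degenerate_genes():
    truth = np.array([[1.0, 5.0, 2.0], [2.0, 5.0, 3.0], [3.0, 5.0, 4.0]])
    ev = np.array([[1, 1, 1], [1, 1, 0], [1, 1, 0]])
    r2 = r2_per_gene(truth, truth * 0.9, ev)
    assert np.isfinite(r2[0])
    assert np.isnan(r2[1])  # zero variance among evaluated entries
    assert np.isnan(r2[2])  # fewer than two evaluated entries


def test_r2_empty_mask_raises():
    with pytest.raises(ValueError, match="no entries"):
        r2_per_gene(np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# Protocol machinery
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def eval_data():
    cfg = SynthConfig(n_genes=15, n_donors=40, latent_rank=3, seed=8)
    return generate_dataset(cfg)


def test_masked_view_poisons_hidden_entries(eval_data):
    data, _ = eval_data
    visible, hidden = _eval_mask_for(1, data.expression.values.shape, 0.5, data.mask.values)
    masked = _masked_view(data, visible)
    assert np.isnan(masked.expression.values[visible == 0]).all()
    assert np.isfinite(masked.expression.values[visible == 1]).all()
    assert (visible + hidden == data.mask.values).all()  # partition of observed
    assert not (visible & hidden).any()


def test_eval_masks_only_cover_observed_entries(eval_data):
    data, _ = eval_data
    base = data.mask.values.copy()
    base[:, 0] = 0  # gene 0 genuinely missing everywhere
    visible, hidden = _eval_mask_for(2, base.shape, 0.5, base)
    assert hidden[:, 0].sum() == 0 and visible[:, 0].sum() == 0


def test_paired_masks_across_methods(eval_data):
    data, truth = eval_data
    seeds = [5, 6]
    rep_a = run_scenario("in_place", data, MedianImputer(), 0.5, 2, seeds)
    rep_b = run_scenario("in_place", data, OracleImputer(truth), 0.5, 2, seeds)
    for ma, mb in zip(rep_a.eval_masks, rep_b.eval_masks):
        np.testing.assert_array_equal(ma, mb)


def test_illegal_truth_read_fails_loudly(eval_data):
    data, _ = eval_data

    class CheatingImputer:
        name = "cheat"
        trainable = False

        def fit(self, train, val=None):
            return self

        def impute(self, d, rng=None):
            return d.expression.values  # reads poisoned entries

    with pytest.raises(AssertionError, match="non-finite"):
        run_scenario("in_place", data, CheatingImputer(), 0.5, 1, [3])


def test_run_scenario_validations(eval_data):
    data, _ = eval_data
    with pytest.raises(ValueError, match="unknown scenario"):
        run_scenario("transductive", data, MedianImputer(), 0.5, 1, [0])
    with pytest.raises(ValueError, match="one seed per"):
        run_scenario("in_place", data, MedianImputer(), 0.5, 2, [0])
    with pytest.raises(ValueError, match="training set"):
        run_scenario("inductive", data, MedianImputer(), 0.5, 1, [0])


class CountingImputer:
    """Trainable stub that counts fits and predicts zero."""

    name = "count"
    trainable = True

    def __init__(self):
        self.fits = 0

    def fit(self, train, val=None):
        self.fits += 1
        return self

    def impute(self, d, rng=None):
        return np.where(d.mask.values == 1, d.observed_values(), 0.0)


def test_in_place_refits_per_repetition(eval_data):
    data, _ = eval_data
    imp = CountingImputer()
    run_scenario("in_place", data, imp, 0.5, 3, [0, 1, 2])
    assert imp.fits == 3


def test_inductive_fits_once(eval_data):
    data, _ = eval_data
    imp = CountingImputer()
    run_scenario("inductive", data, imp, 0.5, 3, [0, 1, 2], train=data)
    assert imp.fits == 1


def test_leakage_hidden_truth_perturbation_changes_nothing(eval_data):
    data, _ = eval_data
    seeds = [7]
    rep_a = run_scenario("in_place", data, MedianImputer(), 0.5, 1, seeds)
    # perturb the truth exactly at the entries that will be hidden
    visible, hidden = _eval_mask_for(7, data.expression.values.shape, 0.5, data.mask.values)
    poked = data.subset_rows(np.arange(data.n_samples))
    poked.expression.values[hidden == 1] += 100.0
    rep_b = run_scenario("in_place", poked, MedianImputer(), 0.5, 1, seeds)
    # identical predictions: the imputer never saw the perturbed truth
    np.testing.assert_array_equal(rep_a.imputed[0], rep_b.imputed[0])


def test_report_aggregates_match_numpy():
    scores = np.array([[0.5, np.nan, 0.2], [0.7, 0.4, 0.0]])
    rep = EvalReport("m", "in_place", 0.5, [0, 1], ["a", "b", "c"], scores)
    np.testing.assert_allclose(rep.per_gene_mean, [0.6, 0.4, 0.1])
    np.testing.assert_allclose(rep.overall_mean_r2, np.mean([0.6, 0.4, 0.1]))
    expected_sd = np.nanmean([np.nanstd(scores[:, g]) for g in range(3)])
    np.testing.assert_allclose(rep.mean_per_gene_sd, expected_sd)
    s = rep.summary()
    assert s["repetitions"] == 2 and s["n_genes_scored"] == 3
    frame = rep.scores_frame()
    assert list(frame.columns) == ["rep0", "rep1"]
    assert frame.shape == (3, 2)


def test_missing_rate_sweep_validations_and_pairing(eval_data):
    data, _ = eval_data
    with pytest.raises(ValueError, match="rates"):
        missing_rate_sweep(data, MedianImputer().fit(data), [0.5, 0.3])
    with pytest.raises(ValueError, match="rates"):
        missing_rate_sweep(data, MedianImputer().fit(data), [0.0, 0.5])
    rates = [0.3, 0.6]
    rep_m = missing_rate_sweep(data, MedianImputer().fit(data), rates, 2, [0, 1])
    rep_k = missing_rate_sweep(data, KNNImputer(3).fit(data), rates, 2, [0, 1])
    assert [r.missing_rate for r in rep_m] == rates
    for a, b in zip(rep_m, rep_k):
        assert a.seeds == b.seeds  # identical masks per rate → paired design
        assert all(0 <= s < 2**31 for s in a.seeds)


def test_aggregate_by_group(eval_data):
    data, truth = eval_data
    rep = run_scenario("in_place", data, MedianImputer(), 0.5, 2, [0, 1])
    groups = np.asarray(data.covariates.labels("tissue"))
    df = aggregate_by_group(rep, groups)
    assert set(df.index) <= set(data.covariates.vocab[0])
    assert int(df["n_samples"].sum()) == data.n_samples
    assert {"mean_r2", "q1", "median", "q3", "iqr"} <= set(df.columns)
    with pytest.raises(ValueError, match="grouping"):
        aggregate_by_group(rep, groups[:-1])
    slim = run_scenario("in_place", data, MedianImputer(), 0.5, 1, [0], keep_arrays=False)
    with pytest.raises(ValueError, match="keep_arrays"):
        aggregate_by_group(slim, groups)
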