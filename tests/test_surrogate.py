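"""Lasso surrogate: splitting, penalized fits, fidelity and ICC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gmnet.cohort import RegionMismatchError
from gmnet.surrogate import (
    SurrogateModel,
    apply_surrogate,
    fit_lasso,
    icc_agreement,
    split_by_subject,
    train_surrogate,
)
from gmnet.synth import simulate_cohort


# --- subject-level split ----------------------------------------------------

def test_split_seventy_thirty(cohort_small):
    table, _ = cohort_small
    sub = table.subset_subjects(table.subjects[:10])
    train, valid = split_by_subject(sub, 0.70, seed=0)
    assert len(train) == 7 and len(valid) == 3


def test_split_deterministic(cohort_small):
    table, _ = cohort_small
    a = split_by_subject(table, seed=5)
    b = split_by_subject(table, seed=5)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_split_fraction_out_of_range(cohort_small):
    with pytest.raises(ValueError):
        split_by_subject(cohort_small[0], fraction=1.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000), frac=st.floats(0.1, 0.9))
def test_split_is_partition_without_leakage(gt_small, seed, frac):
    """No subject ever appears on both sides; sizes track the fraction."""
    table, _ = simulate_cohort(gt_small, n_subjects=4, seed=7)
    train, valid = split_by_subject(table, frac, seed=seed)
    assert set(train) & set(valid) == set()
    assert set(train) | set(valid) == set(table.subjects)
    assert abs(len(train) - frac * table.n_subjects) <= 1


# --- the penalized fit ------------------------------------------------------

def _standardized_X(rng, n, p):
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    return X


def test_lasso_zero_penalty_matches_ols():
    rng = np.random.default_rng(0)
    X = _standardized_X(rng, 200, 5)
    beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    y = X @ beta + rng.normal(0, 0.1, 200)
    coef, b0 = fit_lasso(X, y, 0.0)
    ols = np.linalg.lstsq(np.column_stack([np.ones(200), X]), y, rcond=None)[0]
    np.testing.assert_allclose(coef, ols[1:], atol=1e-6)
    assert b0 == pytest.approx(ols[0], abs=1e-6)


def test_lasso_above_lambda_max_all_zero():
    rng = np.random.default_rng(1)
    X = _standardized_X(rng, 100, 4)
    y = rng.normal(size=100)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / 100
    coef, _ = fit_lasso(X, y, lam_max * 1.001)
    np.testing.assert_array_equal(coef, 0.0)


def test_lasso_univariate_soft_threshold():
    """Single standardized predictor: β = sign(ρ)·max(|ρ|−λ, 0)."""
    x = np.tile([1.0, -1.0], 50)  # mean 0, SD 1 exactly
    y = 0.5 * x
    coef, _ = fit_lasso(x[:, None], y, 0.2)
    assert coef[0] == pytest.approx(0.3, abs=1e-6)


def test_lasso_rejects_nan():
    X = np.array([[1.0], [np.nan]])
    with pytest.raises(ValueError):
        fit_lasso(X, np.array([1.0, 2.0]), 0.1)


def test_lasso_sparsity_monotone_in_penalty():
    rng = np.random.default_rng(2)
    X = _standardized_X(rng, 150, 12)
    y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(0, 0.3, 150)
    grid = np.geomspace(1e-4, 1.0, 15)
    nnz = [np.count_nonzero(fit_lasso(X, y, lam)[0]) for lam in grid]
    assert all(a >= b for a, b in zip(nnz, nnz[1:]))


# --- intra-class correlation ------------------------------------------------

def test_icc_perfect_agreement():
    x = np.arange(10.0)
    assert icc_agreement(x, x) == pytest.approx(1.0)


def test_icc_independent_noise_near_zero():
    rng = np.random.default_rng(3)
    x = rng.normal(size=10_000)
    y = rng.normal(size=10_000)
    assert abs(icc_agreement(x, y)) < 0.1


def test_icc_hand_worked_offset_example():
    """x = 1..6, y = x + 1: ANOVA gives MSR=7, MSC=3, MSE=0 → ICC = 7/8."""
    x = np.arange(1.0, 7.0)
    y = x + 1.0
    icc = icc_agreement(x, y)
    assert icc == pytest.approx(0.875, abs=1e-12)
    r = np.corrcoef(x, y)[0, 1]
    assert icc < r  # absolute agreement penalizes the offset


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    x = rng.normal(size=40)
    y = x + rng.normal(0, 0.4, 40) + 0.2
    df = pd.DataFrame({
        "target": np.r_[np.arange(40), np.arange(40)],
        "rater": ["a"] * 40 + ["b"] * 40,
        "score": np.r_[x, y],
    })
    icc_table = pg.intraclass_corr(
        df, targets="target", raters="rater", ratings="score"
    ).set_index("Type")
    # two-way random, absolute agreement, single measures: ICC2 / ICC(A,1)
    label = "ICC2" if "ICC2" in icc_table.index else "ICC(A,1)"
    ref = icc_table.loc[label, "ICC"]
    assert icc_agreement(x, y) == pytest.approx(ref, abs=1e-9)


def test_icc_degenerate_inputs():
    with pytest.raises(ValueError):
        icc_agreement(np.ones(5), np.ones(5))
    with pytest.raises(ValueError):
        icc_agreement(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


# --- training and applying --------------------------------------------------

def test_surrogate_fidelity_on_held_out_subjects(cohort_small, ica_small):
    model = train_surrogate(cohort_small[0], ica_small, seed=42)
    assert model.icc_validation.min() >= 0.99


def test_surrogate_validation_r2_near_one(cohort_small, ica_small):
    """ICA loadings are affine in volumes, so the surrogate can be near-exact."""
    table = cohort_small[0]
    model = train_surrogate(table, ica_small, seed=42)
    _, valid_ids = split_by_subject(table, 0.70, seed=42)
    mask = table.data["subject_id"].isin(valid_ids).to_numpy()
    pred = model.predict(table.volumes()[mask])
    for k in range(model.K):
        truth = ica_small.loadings[mask, k]
        r2 = 1 - np.sum((truth - pred[:, k]) ** 2) / np.sum((truth - truth.mean()) ** 2)
        assert r2 > 0.999


def test_surrogate_huge_penalty_flagged(cohort_small, ica_small):
    with pytest.raises(ValueError, match="ICC undefined|all-zero"):
        train_surrogate(cohort_small[0], ica_small, lambda_grid=[1e12], seed=0)


def test_apply_equals_fitted_values_on_training_rows(cohort_small, ica_small):
    table = cohort_small[0]
    model = train_surrogate(table, ica_small, seed=42)
    measures = apply_surrogate(model, table)
    np.testing.assert_allclose(
        measures.loadings(), model.predict(table.volumes()), atol=1e-12
    )


def test_apply_region_mismatch_rejected(cohort_small, ica_small):
    table = cohort_small[0]
    model = train_surrogate(table, ica_small, seed=42)
    renamed = table.data.rename(
        columns={table.region_names[0]: "gm_renamed"}
    )
    from gmnet.cohort import CohortTable
    bad = CohortTable(renamed, ["gm_renamed", *table.region_names[1:]])
    with pytest.raises(RegionMismatchError):
        apply_surrogate(model, bad)


def test_unseen_cohort_scored_close_to_direct_projection(gt_small, cohort_small, ica_small):
    """On a fresh cohort, surrogate scores agree with direct ICA projection."""
    model = train_surrogate(cohort_small[0], ica_small, seed=42)
    new_table, _ = simulate_cohort(gt_small, n_subjects=15, seed=777, subject_prefix="N")
    measures = apply_surrogate(model, new_table)
    oracle = ica_small.project(new_table.volumes())
    for k in range(model.K):
        assert icc_agreement(oracle[:, k], measures.loadings()[:, k]) >= 0.99


def test_surrogate_serialization_round_trip(cohort_small, ica_small, tmp_path):
    table = cohort_small[0]
    model = train_surrogate(table, ica_small, seed=42)
    path = tmp_path / "surrogate.json"
    model.to_json(path)
    back = SurrogateModel.from_json(path)
    np.testing.assert_allclose(
        back.predict(table.volumes()), model.predict(table.volumes()), atol=1e-12
    )
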