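"""Mixed models, FDR, APC, trajectories, EDSS models and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gmnet.cohort import NetworkMeasureTable, measures_from_loadings
from gmnet.stats import (
    adjusted_r2,
    annual_pct_change,
    apc_from_slope,
    bh_fdr,
    edss_association,
    fit_lmm,
    phenotype_trajectories,
    stepwise_selection,
    subject_level_edss,
)
from tests.util import match_to_truth


# --- the REML engine --------------------------------------------------------

def test_reml_matches_balanced_anova_closed_form():
    rng = np.random.default_rng(5)
    a, k = 30, 5
    b = rng.normal(0, 1.3, a)
    y = (b[:, None] + rng.normal(0, 0.8, (a, k))).ravel()
    subj = np.repeat(np.arange(a), k)
    res = fit_lmm(y, np.ones((a * k, 1)), subj)
    ybar_i = y.reshape(a, k).mean(axis=1)
    msb = k * ((ybar_i - y.mean()) ** 2).sum() / (a - 1)
    msw = ((y.reshape(a, k) - ybar_i[:, None]) ** 2).sum() / (a * (k - 1))
    assert res.sigma2_resid == pytest.approx(msw, abs=1e-6)
    assert res.sigma2_subject == pytest.approx((msb - msw) / k, abs=1e-6)


def test_reml_zero_between_subject_variance_boundary():
    """Perfectly anti-correlated within-subject values force λ to 0 and β to OLS."""
    a = 40
    subj = np.repeat(np.arange(a), 2)
    rng = np.random.default_rng(6)
    c = rng.uniform(0.5, 1.5, a)
    y = np.column_stack([c, -c]).ravel()  # every subject mean exactly 0
    X = np.column_stack([np.ones(2 * a), rng.normal(size=2 * a)])
    res = fit_lmm(y, X, subj)
    assert res.sigma2_subject < 1e-6 * res.sigma2_resid
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(res.beta, ols, atol=1e-8)


def test_lmm_rejects_bad_designs():
    subj = np.repeat(np.arange(10), 2)
    y = np.arange(20.0)
    X = np.column_stack([np.ones(20), np.ones(20)])
    with pytest.raises(ValueError, match="singular"):
        fit_lmm(y, X, subj)
    with pytest.raises(ValueError, match="too few"):
        fit_lmm(y[:4], np.column_stack([np.ones(4), np.arange(4.0)]), subj[:4])


def test_ci_contract_exact():
    rng = np.random.default_rng(7)
    subj = np.repeat(np.arange(25), 4)
    X = np.column_stack([np.ones(100), rng.normal(size=100)])
    y = X @ [1.0, 0.5] + rng.normal(0, 1, 25)[subj] + rng.normal(0, 1, 100)
    res = fit_lmm(y, X, subj)
    np.testing.assert_array_equal(res.ci95[:, 0], res.beta - 1.96 * res.se)
    np.testing.assert_array_equal(res.ci95[:, 1], res.beta + 1.96 * res.se)
    assert ((res.p_wald >= 0) & (res.p_wald <= 1)).all()
    assert res.sigma2_subject >= 0 and res.sigma2_resid >= 0


# --- Benjamini–Hochberg -----------------------------------------------------

def test_bh_all_ones_no_rejection():
    q, rej = bh_fdr(np.ones(6))
    assert not rej.any()
    np.testing.assert_array_equal(q, 1.0)


def test_bh_hand_worked_step_up():
    """p = (.01,.02,.2,.9): thresholds .0125/.025/.0375/.05 → 2 rejections."""
    q, rej = bh_fdr(np.array([0.01, 0.02, 0.2, 0.9]))
    assert rej.tolist() == [True, True, False, False]
    np.testing.assert_allclose(q, [0.04, 0.04, 4 / 15, 0.9], atol=1e-12)
    assert (q >= np.array([0.01, 0.02, 0.2, 0.9])).all()


def test_bh_empty_rejected():
    with pytest.raises(ValueError):
        bh_fdr(np.array([]))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
def test_bh_rejections_nested_in_alpha(pvals):
    p = np.asarray(pvals)
    _, rej_small = bh_fdr(p, alpha=0.01)
    _, rej_large = bh_fdr(p, alpha=0.10)
    assert (rej_large | ~rej_small).all()  # rejections at 0.01 ⊆ at 0.10


# --- annual percentage change ----------------------------------------------

def test_apc_arithmetic_and_guards():
    assert apc_from_slope(0.0, 2.0)["apc"] == 0.0
    out = apc_from_slope(-0.04, 2.0)
    assert out["apc"] == pytest.approx(-2.0)
    assert out["percentage"]
    tiny = apc_from_slope(-0.04, 1e-9, measure_sd=1.0)
    assert not tiny["percentage"]
    assert tiny["apc"] == -0.04


def test_apc_requires_slope_term():
    rng = np.random.default_rng(8)
    subj = np.repeat(np.arange(20), 3)
    X = np.column_stack([np.ones(60), np.tile(np.arange(3.0), 20)])
    y = rng.normal(size=60) + rng.normal(size=20)[subj]
    res = fit_lmm(y, X, subj, terms=["const", "time_years"])
    out = annual_pct_change(res, "time_years", baseline_mean=2.0)
    assert out["percentage"]
    with pytest.raises(ValueError):
        annual_pct_change(res, "nope", baseline_mean=2.0)


# --- phenotype trajectories -------------------------------------------------

def test_reference_switch_maps_contrasts_exactly(measures_small, cohort_small):
    r_sp = phenotype_trajectories(measures_small, cohort_small[0], reference="SP")
    r_rr = phenotype_trajectories(measures_small, cohort_small[0], reference="RR")
    for out in ["loading_1", "gm_total"]:
        assert r_sp.results[out]["phen_RR"]["beta"] == pytest.approx(
            -r_rr.results[out]["phen_SP"]["beta"], rel=1e-8, abs=1e-8
        )
        assert r_sp.results[out]["phen_RR:time"]["beta"] == pytest.approx(
            -r_rr.results[out]["phen_SP:time"]["beta"], rel=1e-8, abs=1e-8
        )


def test_missing_reference_phenotype_rejected(measures_small, cohort_small):
    with pytest.raises(ValueError, match="absent"):
        phenotype_trajectories(measures_small, cohort_small[0], reference="XX")


def test_trajectory_q_at_least_p(measures_small, cohort_small):
    rep = phenotype_trajectories(measures_small, cohort_small[0])
    assert (rep.table["q"] >= rep.table["p"] - 1e-15).all()
    assert set(rep.apc["group"]) == {"RR", "SP", "PP"}


def test_interaction_estimates_calibrated_to_planted_slopes(
    gt_default, cohort_default, ica_default, measures_default
):
    """RR-vs-SP slope contrasts recover planted drift differences (rescaled)."""
    table, lat = cohort_default
    rep = phenotype_trajectories(measures_default, table, reference="SP")
    perm, _ = match_to_truth(ica_default.maps, gt_default.maps_true)
    for k_true in range(gt_default.K_true):
        col = f"loading_{perm[k_true] + 1}"
        latent = lat[f"l_{k_true + 1}"].to_numpy()
        loading = measures_default.data[col].to_numpy()
        scale = np.polyfit(latent, loading, 1)[0]  # ICA units per mm³
        expected = (gt_default.slope["RR"][k_true] - gt_default.slope["SP"][k_true]) * scale
        est = rep.results[col]["phen_RR:time"]
        assert abs(est["beta"] - expected) < 5 * est["se"]
        row = rep.table.query(
            "measure == @col and family == 'slope:RR_vs_SP'"
        ).iloc[0]
        if abs(expected) > 6 * est["se"]:
            assert row["significant"]


# --- EDSS associations ------------------------------------------------------

def test_edss_scale_invariance_of_zscored_models(measures_small, cohort_small):
    doubled = measures_small.data.copy()
    doubled["loading_2"] = 2.0 * doubled["loading_2"]
    mt = NetworkMeasureTable(doubled, list(measures_small.loading_columns))
    a = edss_association(measures_small, cohort_small[0])
    b = edss_association(mt, cohort_small[0])
    pa = a.table.query("measure == 'loading_2'")["p"].to_numpy()
    pb = b.table.query("measure == 'loading_2'")["p"].to_numpy()
    np.testing.assert_allclose(pa, pb, rtol=1e-9)


def test_edss_baseline_effects_strongest_for_clinical_networks(
    gt_default, cohort_default, ica_default, measures_default
):
    rep = edss_association(measures_default, cohort_default[0])
    perm, _ = match_to_truth(ica_default.maps, gt_default.maps_true)
    clin_cols = {f"loading_{perm[k] + 1}" for k in gt_default.clinical_networks}
    base = rep.table.query("family == 'baseline' and measure != 'gm_total'")
    top = set(base.reindex(base["beta"].abs().sort_values().index)
              .tail(len(clin_cols))["measure"])
    assert top == clin_cols
    assert base[base["measure"].isin(clin_cols)]["significant"].all()


def test_edss_pure_noise_rarely_rejected(gt_small):
    """With no clinical coupling, EDSS models reject at roughly the FDR level."""
    from gmnet.synth import SynthConfig, make_ground_truth, simulate_cohort

    cfg = SynthConfig(n_regions=40, k_networks=4, support_min=3, support_max=8,
                      n_clinical_networks=0)
    total = 0
    for rep in range(10):
        gt = make_ground_truth(cfg, seed=500 + rep)
        table, lat = simulate_cohort(gt, n_subjects=15, seed=600 + rep)
        meas = measures_from_loadings(
            table, lat[[f"l_{k}" for k in range(1, 5)]].to_numpy()
        )
        out = edss_association(meas, table)
        total += int(out.table.query("measure != 'gm_total'")["significant"].sum())
    # 10 replicates x 2 families x 4 networks; BH keeps false flags rare
    assert total <= 8


def test_edss_rows_dropped_only_when_missing(measures_small, cohort_small):
    rep = edss_association(measures_small, cohort_small[0])
    n_obs = rep.results["gm_total"].n_obs
    assert n_obs == cohort_small[0].data["edss"].notna().sum()


# --- stepwise selection -----------------------------------------------------

def test_adjusted_r2_formula():
    assert adjusted_r2(0.5, n=20, p=3) == pytest.approx(0.40625, abs=1e-12)


def test_stepwise_selects_true_predictor_among_noise():
    hits = 0
    for rep in range(10):
        rng = np.random.default_rng(900 + rep)
        n = 2000
        df = pd.DataFrame({f"c{i}": rng.normal(size=n) for i in range(8)})
        df["age"] = rng.uniform(30, 60, n)
        df["y"] = 0.5 * df["c0"] + 0.02 * df["age"] + rng.normal(0, 1, n)
        out = stepwise_selection(df, "y", [f"c{i}" for i in range(8)], ["age"])
        hits += out["selected"] == ["c0"] or set(out["selected"]) >= {"c0"}
        assert "age" in out["terms"]
    assert hits >= 9


def test_stepwise_empty_candidates_returns_covariate_model():
    rng = np.random.default_rng(10)
    df = pd.DataFrame({"y": rng.normal(size=50), "age": rng.normal(size=50)})
    out = stepwise_selection(df, "y", [], ["age"])
    assert out["selected"] == []
    assert "age" in out["terms"]


def test_stepwise_underdetermined_rejected():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({f"c{i}": rng.normal(size=6) for i in range(8)})
    df["y"] = rng.normal(size=6)
    with pytest.raises(ValueError, match="n <= p"):
        stepwise_selection(df, "y", [f"c{i}" for i in range(8)], [])


def test_subject_level_edss_summaries(cohort_small):
    table, _ = cohort_small
    subj = subject_level_edss(table)
    assert len(subj) == table.n_subjects
    assert (subj["n_visits"] == 4).all()
    # a subject with steadily rising EDSS must get a positive slope
    any_slope = subj["edss_slope"].dropna()
    assert len(any_slope) > 0
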