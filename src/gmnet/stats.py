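"""Linear mixed models and the longitudinal analysis families.

Three analysis families operate on the (harmonized) network measures:

* phenotype trajectories — per-network mixed models of the loading on
  phenotype, time and their interaction, with baseline age, sex, disease
  duration, TIV and treatment as covariates;
* EDSS associations — mixed models of EDSS on z-scored loading, time and
  their interaction with the same covariates (baseline term = loading main
  effect, progression term = loading × time);
* stepwise selection — bidirectional AIC selection over network measures
  plus whole-brain GM for baseline EDSS or per-subject EDSS change, with
  forced covariates always retained.

All models use a subject random intercept plus residual ("visit nested in
subject" with one observation per visit is exactly this structure: a
visit-level random effect would be confounded with the residual), REML
estimation and Wald z inference.  Multiple comparisons are corrected by
Benjamini–Hochberg FDR within each contrast family across networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from gmnet.cohort import CohortTable, NetworkMeasureTable

__all__ = [
    "MixedModelResult",
    "AnalysisReport",
    "fit_lmm",
    "bh_fdr",
    "annual_pct_change",
    "phenotype_trajectories",
    "edss_association",
    "stepwise_selection",
    "subject_level_edss",
]


@dataclass
class MixedModelResult:
    """Fixed effects and variance components from a random-intercept LMM."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    ci95: np.ndarray           # len(terms) x 2, beta ± 1.96 se
    p_wald: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    n_obs: int
    n_subjects: int
    converged: bool

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "ci95": (float(self.ci95[i, 0]), float(self.ci95[i, 1])),
            "p": float(self.p_wald[i]),
        }


@dataclass
class AnalysisReport:
    """Per-network model results plus FDR-corrected contrast tables.

    ``table`` has one row per (measure, family, term) with beta, se, CI,
    raw p, BH-adjusted q and a significance flag; ``apc`` holds annual
    percentage change summaries where the analysis defines them.
    """

    results: dict
    table: pd.DataFrame
    apc: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _reml_pieces(lam, XtX, Xty, yty, Gx, Gy, sizes, n, p):
    """GLS quantities at variance ratio lam = sigma2_subject / sigma2_resid.

    For a subject with n_i rows, V_i^{-1} ∝ I − c_i·11ᵀ with
    c_i = lam / (1 + n_i lam); all products reduce to per-subject sums.
    """
    c = lam / (1.0 + sizes * lam)
    A = XtX - (Gx * c[:, None]).T @ Gx
    rhs = Xty - Gx.T @ (c * Gy)
    beta = np.linalg.solve(A, rhs)
    # rᵀV⁻¹r with r = y − Xβ, via precomputed cross-products
    Gr = Gy - Gx @ beta
    q = (yty - 2 * beta @ Xty + beta @ XtX @ beta) - c @ (Gr ** 2)
    sigma2 = q / (n - p)
    logdet_v = np.sum(np.log1p(sizes * lam))
    sign, logdet_a = np.linalg.slogdet(A)
    crit = (n - p) * np.log(max(sigma2, 1e-300)) + logdet_v + logdet_a
    return crit, beta, sigma2, A


def fit_lmm(y, X, subject_ids, terms=None) -> MixedModelResult:
    """REML random-intercept linear mixed model with Wald z inference.

    The REML criterion is profiled down to one dimension — the variance
    ratio λ = σ²_subject/σ²_resid — and minimized by Brent search after a
    log-spaced bracketing scan; β is then the GLS solution at λ̂.  ``X``
    must include the intercept column.  95% CIs are beta ± 1.96 se.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    subject_ids = np.asarray(subject_ids)
    n, p = X.shape
    if terms is None:
        terms = [f"x{i}" for i in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    if n <= p + 2:
        raise ValueError("too few observations for the design")

    order = np.argsort(subject_ids, kind="stable")
    Xs, ys, ss = X[order], y[order], subject_ids[order]
    _, starts = np.unique(ss, return_index=True)
    sizes = np.diff(np.append(starts, n)).astype(float)
    Gx = np.add.reduceat(Xs, starts, axis=0)
    Gy = np.add.reduceat(ys, starts)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    def crit(lam):
        return _reml_pieces(lam, XtX, Xty, yty, Gx, Gy, sizes, n, p)[0]

    # bracket the minimum on a log grid (plus the boundary lam = 0)
    grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e8, 65)])
    vals = [crit(g) for g in grid]
    j = int(np.argmin(vals))
    if j == 0:
        lo, hi = 0.0, grid[1]
    else:
        lo = grid[j - 1]
        hi = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12 * max(1.0, grid[j])})
    lam_hat = float(res.x) if res.fun <= vals[j] else float(grid[j])

    _, beta, sigma2, A = _reml_pieces(lam_hat, XtX, Xty, yty, Gx, Gy, sizes, n, p)
    cov_beta = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * sps.norm.sf(np.abs(z))
    ci = np.column_stack([beta - 1.96 * se, beta + 1.96 * se])
    return MixedModelResult(
        terms=list(terms),
        beta=beta,
        se=se,
        ci95=ci,
        p_wald=pvals,
        sigma2_subject=float(lam_hat * sigma2),
        sigma2_resid=float(sigma2),
        n_obs=int(n),
        n_subjects=len(starts),
        converged=True,
    )


def bh_fdr(p, alpha: float = 0.05):
    """Benjamini–Hochberg step-up: returns (q-values, reject flags)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def annual_pct_change(
    result: MixedModelResult,
    slope_term: str,
    baseline_mean: float,
    measure_sd: float | None = None,
    eps: float = 1e-6,
) -> dict:
    """Annual percentage change: 100 · slope / |baseline mean|.

    If the baseline mean is negligible relative to the measure's SD the
    percentage is meaningless; the absolute slope is returned instead with
    ``percentage=False``.
    """
    if slope_term not in result.terms:
        raise ValueError(f"slope term {slope_term!r} not in model")
    slope = result[slope_term]["beta"]
    return apc_from_slope(slope, baseline_mean, measure_sd, eps)


def apc_from_slope(slope, baseline_mean, measure_sd=None, eps=1e-6) -> dict:
    guard = eps * measure_sd if measure_sd is not None else eps
    if abs(baseline_mean) <= guard:
        return {"apc": float(slope), "percentage": False, "slope": float(slope)}
    return {
        "apc": float(100.0 * slope / abs(baseline_mean)),
        "percentage": True,
        "slope": float(slope),
    }


# ---------------------------------------------------------------------------
# shared design helpers

_COVARIATES = ["age_baseline", "sex_M", "disease_duration", "tiv", "treated"]


def merge_measures(measures: NetworkMeasureTable, cohort: CohortTable) -> pd.DataFrame:
    cov = cohort.data[
        ["subject_id", "visit_index", "time_years", "phenotype", "arm",
         "age_baseline", "sex", "disease_duration", "tiv", "edss", "site_id"]
    ]
    df = measures.data.merge(cov, on=["subject_id", "visit_index"], validate="1:1")
    if len(df) != len(measures.data):
        raise ValueError("measures and cohort rows do not align")
    df["sex_M"] = (df["sex"] == "M").astype(float)
    df["treated"] = (df["arm"] == "treated").astype(float)
    return df


def phenotype_trajectories(
    measures: NetworkMeasureTable,
    cohort: CohortTable,
    reference: str = "SP",
    alpha: float = 0.05,
) -> AnalysisReport:
    """Phenotype × time mixed models for every network and whole-brain GM.

    Baseline contrasts are the phenotype main effects against ``reference``;
    slope contrasts are the phenotype × time interactions.  BH-FDR is applied
    across the K+1 outcomes within each contrast family.  Annual percentage
    change is reported per phenotype group from the fitted group slopes and
    the group's observed baseline means.
    """
    df = merge_measures(measures, cohort)
    phens = [p for p in ("RR", "SP", "PP") if p in set(df["phenotype"])]
    if reference not in phens:
        raise ValueError(f"reference phenotype {reference!r} absent from data")
    if len(phens) < 2:
        raise ValueError("need at least 2 phenotypes")
    others = [p for p in phens if p != reference]

    outcomes = [*measures.loading_columns, "gm_total"]
    terms = ["const"]
    terms += [f"phen_{p}" for p in others]
    terms += ["time_years"]
    terms += [f"phen_{p}:time" for p in others]
    terms += _COVARIATES

    X = np.column_stack(
        [np.ones(len(df))]
        + [(df["phenotype"] == p).astype(float) for p in others]
        + [df["time_years"]]
        + [(df["phenotype"] == p).astype(float) * df["time_years"] for p in others]
        + [df[c] for c in _COVARIATES]
    )
    # drop constant covariate columns (e.g. all-untreated cohorts)
    keep = [i for i in range(X.shape[1]) if i == 0 or X[:, i].std() > 0]
    X = X[:, keep]
    terms = [terms[i] for i in keep]

    results: dict = {}
    rows = []
    apc_rows = []
    for out in outcomes:
        res = fit_lmm(df[out], X, df["subject_id"], terms)
        results[out] = res
        for p in others:
            for fam, term in (
                (f"baseline:{p}_vs_{reference}", f"phen_{p}"),
                (f"slope:{p}_vs_{reference}", f"phen_{p}:time"),
            ):
                t = res[term]
                rows.append({"measure": out, "family": fam, "term": term, **{
                    "beta": t["beta"], "se": t["se"],
                    "ci_lo": t["ci95"][0], "ci_hi": t["ci95"][1], "p": t["p"]}})
        # per-phenotype APC from group slope and baseline mean
        sd = float(df[out].std())
        for p in phens:
            slope = res["time_years"]["beta"]
            if p != reference:
                slope += res[f"phen_{p}:time"]["beta"]
            base = df.loc[(df["phenotype"] == p) & (df["time_years"] == 0), out]
            a = apc_from_slope(slope, float(base.mean()), sd)
            apc_rows.append({"measure": out, "group": p, **a})

    table = pd.DataFrame(rows)
    table = _fdr_by_family(table, alpha)
    return AnalysisReport(
        results=results,
        table=table,
        apc=pd.DataFrame(apc_rows),
        meta={"reference": reference, "alpha": alpha},
    )


def edss_association(
    measures: NetworkMeasureTable,
    cohort: CohortTable,
    networks=None,
    alpha: float = 0.05,
    zscore: bool = True,
) -> AnalysisReport:
    """EDSS mixed models: loading (z-scored), time and their interaction.

    ``networks`` selects the loading columns to test (default: all, plus
    whole-brain GM — callers restrict to the clinically motivated subset).
    Rows with missing EDSS are dropped per analysis (complete case); the
    loading main effect is the baseline association and loading × time the
    progression association, each an FDR family across measures.
    """
    df = merge_measures(measures, cohort)
    df = df.dropna(subset=["edss"])
    if len(df) == 0:
        raise ValueError("no rows with observed EDSS")
    if networks is None:
        sel = [*measures.loading_columns]
    else:
        sel = [c if isinstance(c, str) else measures.loading_columns[c] for c in networks]
    outcomes = [*sel, "gm_total"]

    results: dict = {}
    rows = []
    for out in outcomes:
        x = df[out].astype(float)
        if zscore:
            if x.std(ddof=0) == 0:
                raise ValueError(f"zero variance measure {out!r}")
            x = (x - x.mean()) / x.std(ddof=0)
        cols = [np.ones(len(df)), x, df["time_years"], x * df["time_years"]]
        terms = ["const", "loading", "time_years", "loading:time"]
        for c in _COVARIATES:
            if df[c].std() > 0:
                cols.append(df[c])
                terms.append(c)
        res = fit_lmm(df["edss"], np.column_stack(cols), df["subject_id"], terms)
        results[out] = res
        for fam, term in (("baseline", "loading"), ("progression", "loading:time")):
            t = res[term]
            rows.append({"measure": out, "family": fam, "term": term,
                         "beta": t["beta"], "se": t["se"],
                         "ci_lo": t["ci95"][0], "ci_hi": t["ci95"][1], "p": t["p"]})

    table = _fdr_by_family(pd.DataFrame(rows), alpha)
    return AnalysisReport(results=results, table=table,
                          meta={"alpha": alpha, "zscored": zscore})


def _fdr_by_family(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    table = table.copy()
    table["q"] = np.nan
    table["significant"] = False
    for fam, idx in table.groupby("family").groups.items():
        q, rej = bh_fdr(table.loc[idx, "p"].to_numpy(), alpha)
        table.loc[idx, "q"] = q
        table.loc[idx, "significant"] = rej
    return table


def subject_level_edss(cohort: CohortTable) -> pd.DataFrame:
    """One row per subject: baseline EDSS, OLS EDSS slope over time, covariates.

    Subjects need >= 2 observed EDSS values for a slope (else NaN); the
    number of visits is retained as a stepwise covariate.
    """
    recs = []
    for subj, g in cohort.data.groupby("subject_id", sort=True):
        obs = g.dropna(subset=["edss"])
        base = g.loc[g["time_years"] == 0, "edss"]
        slope = np.nan
        if len(obs) >= 2 and obs["time_years"].nunique() > 1:
            slope = float(np.polyfit(obs["time_years"], obs["edss"], 1)[0])
        recs.append({
            "subject_id": subj,
            "edss_baseline": float(base.iloc[0]) if len(base) and not np.isnan(base.iloc[0]) else np.nan,
            "edss_slope": slope,
            "n_visits": len(g),
            "age_baseline": float(g["age_baseline"].iloc[0]),
            "sex_M": float(g["sex"].iloc[0] == "M"),
            "disease_duration": float(g["disease_duration"].iloc[0]),
            "tiv": float(g["tiv"].iloc[0]),
            "treated": float(g["arm"].iloc[0] == "treated"),
        })
    return pd.DataFrame(recs)


def stepwise_selection(
    data: pd.DataFrame,
    outcome: str,
    candidates: list,
    forced: list,
) -> dict:
    """Bidirectional stepwise OLS by AIC with forced covariates retained.

    Starts from the covariate-only model; at each step the single add/drop of
    a candidate that most lowers AIC is taken, until no move improves.
    Returns selected candidates, all final terms and the adjusted R².
    """
    if len(candidates) == 0:
        sel: list = []
        res = _ols(data, outcome, forced)
        return _stepwise_out(sel, forced, res, data, outcome)
    df = data.dropna(subset=[outcome, *candidates, *forced]).reset_index(drop=True)
    n = len(df)
    p_full = 1 + len(candidates) + len(forced)
    if n <= p_full:
        raise ValueError("n <= p for the full candidate model")

    included: list = []
    current = _ols(df, outcome, forced)
    current_aic = current.aic
    while True:
        moves = []
        for c in candidates:
            if c not in included:
                moves.append(("add", c, _ols(df, outcome, forced + included + [c])))
        for c in included:
            rest = [x for x in included if x != c]
            moves.append(("drop", c, _ols(df, outcome, forced + rest)))
        if not moves:
            break
        kind, c, best = min(moves, key=lambda m: m[2].aic)
        if best.aic < current_aic - 1e-9:
            included = included + [c] if kind == "add" else [x for x in included if x != c]
            current, current_aic = best, best.aic
        else:
            break
    return _stepwise_out(included, forced, current, df, outcome)


def _ols(df, outcome, terms):
    X = sm.add_constant(df[terms].astype(float)) if terms else \
        pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.OLS(df[outcome].astype(float), X, missing="drop").fit()


def _stepwise_out(selected, forced, res, df, outcome):
    n = int(res.nobs)
    p = len(res.params) - 1
    r2 = res.rsquared
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    return {
        "selected": list(selected),
        "forced": list(forced),
        "terms": list(res.params.index),
        "r2": float(r2),
        "adjusted_r2": float(adj),
        "aic": float(res.aic),
        "params": {k: float(v) for k, v in res.params.items()},
        "n": n,
    }


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)
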