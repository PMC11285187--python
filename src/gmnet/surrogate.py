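"""Per-network Lasso surrogates: prospective scoring of ICA network measures.

ICA can only be estimated on a whole cohort at once, so its loadings cannot
be computed for new participants or visits without refitting.  The surrogate
is one sparse linear model per network, trained to predict the ICA loading
from the same regional volumes, validated on a held-out subject split by
intra-class correlation, and serialized (with its frozen standardization
parameters) for application to unseen cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import GroupKFold

from gmnet.cohort import (
    CohortTable,
    NetworkMeasureTable,
    RegionMismatchError,
    measures_from_loadings,
)
from gmnet.ica import ICADecomposition

__all__ = [
    "SurrogateModel",
    "split_by_subject",
    "fit_lasso",
    "train_surrogate",
    "apply_surrogate",
    "icc_agreement",
]

logger = logging.getLogger(__name__)


@dataclass
class SurrogateModel:
    """Sparse linear scoring rules for K networks over R regions.

    Prediction for network k is affine in the input volumes:
    ``loading_k = intercept_k + coef_k @ (v - mean_r) / sd_r``.
    Standardization parameters come from the training split and are frozen;
    prospective application never re-estimates anything.
    """

    region_names: list
    coef: np.ndarray          # K x R
    intercept: np.ndarray     # K
    lambda_: np.ndarray       # K, selected penalty per network
    mean_r: np.ndarray        # training-split per-region mean
    sd_r: np.ndarray          # training-split per-region SD
    split_seed: int
    icc_validation: np.ndarray  # K, held-out ICC vs direct ICA loadings

    @property
    def K(self) -> int:
        return len(self.intercept)

    def predict(self, volumes: np.ndarray) -> np.ndarray:
        Z = (np.asarray(volumes, dtype=float) - self.mean_r) / self.sd_r
        return Z @ self.coef.T + self.intercept

    def to_json(self, path) -> None:
        d = {
            "region_names": list(self.region_names),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "lambda_": self.lambda_.tolist(),
            "mean_r": self.mean_r.tolist(),
            "sd_r": self.sd_r.tolist(),
            "split_seed": int(self.split_seed),
            "icc_validation": self.icc_validation.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("coef", "intercept", "lambda_", "mean_r", "sd_r", "icc_validation"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def split_by_subject(table: CohortTable, fraction: float = 0.70, seed: int = 0):
    """Partition subject IDs into train/validation sets (all visits together).

    The split is by participant, never by row, so no subject contributes
    visits to both sides.  |train| is round(fraction * n_subjects); the
    partition is deterministic given ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    subjects = np.sort(np.asarray(table.subjects))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = int(round(fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train = np.sort(subjects[perm[:n_train]])
    valid = np.sort(subjects[perm[n_train:]])
    return train, valid


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float):
    """L1-penalized least squares: (1/2n)‖y − Xβ − β0‖² + λ‖β‖₁.

    ``X`` is expected column-standardized (mean 0, SD 1, 1/n convention).
    Zero-variance columns are dropped (coefficient 0) with a warning;
    λ = 0 falls back to ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in Lasso inputs")
    keep = X.std(axis=0) > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance columns", (~keep).sum())
    Xk = X[:, keep]
    if lam == 0:
        model = LinearRegression().fit(Xk, y)
    else:
        model = Lasso(alpha=lam, fit_intercept=True, tol=1e-7, max_iter=100000).fit(Xk, y)
    coef = np.zeros(X.shape[1])
    coef[keep] = model.coef_
    return coef, float(model.intercept_)


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 30) -> np.ndarray:
    """Log grid from λ_max (smallest penalty zeroing all coefficients) down 4 decades."""
    n = len(y)
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / n
    return np.geomspace(lam_max, lam_max * 1e-4, n_points)


def train_surrogate(
    table: CohortTable,
    ica: ICADecomposition,
    lambda_grid=None,
    cv_folds: int = 5,
    fraction: float = 0.70,
    seed: int = 0,
) -> SurrogateModel:
    """Train one Lasso per network on a 70% subject split; validate on the rest.

    λ is chosen per network by subject-grouped ``cv_folds``-fold
    cross-validation on the training split, minimizing mean squared error,
    then the model is refit on the whole training split.  Fidelity is the
    ICC(2,1) between direct ICA loadings and surrogate predictions on the
    held-out 30%.
    """
    if ica.loadings.shape[0] != table.n_obs:
        raise ValueError("ICA loadings are not aligned with the cohort rows")
    train_ids, valid_ids = split_by_subject(table, fraction, seed)
    subj = table.data["subject_id"].to_numpy()
    tr = np.isin(subj, train_ids)
    va = ~tr

    V = table.volumes()
    mean_r = V[tr].mean(axis=0)
    sd_r = V[tr].std(axis=0)
    if (sd_r == 0).any():
        raise ValueError("zero training SD for some regions; cannot standardize")
    Z = (V - mean_r) / sd_r

    if cv_folds > len(train_ids):
        raise ValueError("fewer training subjects than CV folds")

    K = ica.K
    coefs = np.zeros((K, V.shape[1]))
    intercepts = np.zeros(K)
    lambdas = np.zeros(K)
    iccs = np.zeros(K)
    groups = subj[tr]
    gkf = GroupKFold(n_splits=cv_folds)
    folds = list(gkf.split(Z[tr], groups=groups))

    for k in range(K):
        y = ica.loadings[:, k]
        grid = (
            np.asarray(lambda_grid, dtype=float)
            if lambda_grid is not None
            else default_lambda_grid(Z[tr], y[tr])
        )
        if grid.size == 0:
            raise ValueError("empty lambda grid")
        mse = np.zeros(len(grid))
        for tr_idx, te_idx in folds:
            Xf, yf = Z[tr][tr_idx], y[tr][tr_idx]
            Xt, yt = Z[tr][te_idx], y[tr][te_idx]
            for j, lam in enumerate(grid):
                c, b0 = fit_lasso(Xf, yf, lam)
                mse[j] += np.mean((yt - Xt @ c - b0) ** 2)
        lam_k = float(grid[int(np.argmin(mse))])
        coefs[k], intercepts[k] = fit_lasso(Z[tr], y[tr], lam_k)
        lambdas[k] = lam_k

        pred_va = Z[va] @ coefs[k] + intercepts[k]
        if np.std(pred_va) == 0:
            raise ValueError(
                f"network {k}: all-zero surrogate (penalty too large); ICC undefined"
            )
        iccs[k] = icc_agreement(y[va], pred_va)

    return SurrogateModel(
        region_names=list(table.region_names),
        coef=coefs,
        intercept=intercepts,
        lambda_=lambdas,
        mean_r=mean_r,
        sd_r=sd_r,
        split_seed=seed,
        icc_validation=iccs,
    )


def apply_surrogate(model: SurrogateModel, table: CohortTable) -> NetworkMeasureTable:
    """Score a cohort with a fitted surrogate; no parameter re-estimation."""
    if list(table.region_names) != list(model.region_names):
        raise RegionMismatchError(
            "cohort region names/order do not match the surrogate model"
        )
    loadings = model.predict(table.volumes())
    return NetworkMeasureTable(
        measures_from_loadings(table, loadings).data,
        [f"loading_{k + 1}" for k in range(model.K)],
    )


def icc_agreement(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Shrout–Fleiss with k = 2 raters:
    ``(MS_R − MS_E) / (MS_R + MS_E + 2 (MS_C − MS_E) / n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    d = np.column_stack([x, y])
    grand = d.mean()
    if np.allclose(d, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_mean = d.mean(axis=1)
    col_mean = d.mean(axis=0)
    ss_total = ((d - grand) ** 2).sum()
    ss_rows = 2 * ((row_mean - grand) ** 2).sum()
    ss_cols = n * ((col_mean - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / 1.0
    mse = ss_err / (n - 1)
    return float((msr - mse) / (msr + mse + 2.0 * (msc - mse) / n))
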