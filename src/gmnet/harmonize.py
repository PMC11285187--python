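"""Parametric ComBat harmonization of network measures across sites/scanners.

ComBat models each feature y_jg for sample j in batch i as

    y = alpha_g + X beta_g + gamma_ig + delta_ig * e,   e ~ N(0, sigma_g^2)

and shrinks the per-batch location (gamma) and scale (delta) estimates toward
common priors by empirical Bayes — a normal prior on gamma and an
inverse-gamma prior on delta² with hyperparameters estimated across features.
Adjusted values are ``y* = sigma_g / delta* (z − gamma*) + alpha_g + X beta_g``
where z is the standardized residual.  Biological covariate effects (the
X beta_g term) are estimated jointly with batch and added back untouched.

Applied here to the network loading measures and whole-brain GM (not raw
regional volumes), after surrogate scoring and before the statistical models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gmnet.cohort import NetworkMeasureTable

__all__ = ["CombatFit", "combat_fit_transform"]


@dataclass
class CombatFit:
    """Fitted ComBat parameters for features (columns) across batches."""

    feature_names: list
    batch_labels: list
    alpha: np.ndarray        # G grand intercepts
    beta: np.ndarray         # p x G covariate effects (p may be 0)
    sigma: np.ndarray        # G pooled residual SDs
    gamma_star: np.ndarray   # B x G EB batch locations
    delta_star: np.ndarray   # B x G EB batch scales
    gamma_bar: np.ndarray    # B prior means
    tau2: np.ndarray         # B prior variances
    lambda_prior: np.ndarray  # B inverse-gamma shape
    theta_prior: np.ndarray  # B inverse-gamma scale
    n_iter: int

    def to_json(self, path) -> None:
        d = {
            "feature_names": list(self.feature_names),
            "batch_labels": list(self.batch_labels),
            "n_iter": int(self.n_iter),
        }
        for key in ("alpha", "beta", "sigma", "gamma_star", "delta_star",
                    "gamma_bar", "tau2", "lambda_prior", "theta_prior"):
            d[key] = getattr(self, key).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)


def _eb_iterate(z, gamma_hat, delta2_hat, gamma_bar, tau2, lam, theta,
                tol=1e-6, max_iter=500):
    """Iterate the coupled EB posterior equations for one batch."""
    n = z.shape[0]
    gamma = gamma_hat.copy()
    delta2 = delta2_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        gamma_new = (n * tau2 * gamma_hat + delta2 * gamma_bar) / (n * tau2 + delta2)
        ss = ((z - gamma_new) ** 2).sum(axis=0)
        delta2_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma)), np.max(np.abs(delta2_new - delta2))
        )
        gamma, delta2 = gamma_new, delta2_new
        if change < tol:
            break
    return gamma, delta2, it


def combat_fit_transform(
    measures: NetworkMeasureTable,
    batch,
    covariates=None,
) -> tuple[NetworkMeasureTable, CombatFit]:
    """Harmonize loading columns and whole-brain GM across batches.

    Parameters
    ----------
    measures
        Network measure table; all loading columns plus ``gm_total`` are
        harmonized.
    batch
        Per-row batch (site/scanner) labels aligned with the table.
    covariates
        Optional n × p design of biological covariates to preserve
        (no intercept column; full rank, not confounded with batch).

    With a single batch the data are returned unchanged (gamma* = 0,
    delta* = 1): there is nothing to harmonize.
    """
    features = [*measures.loading_columns, "gm_total"]
    Y = measures.data[features].to_numpy(dtype=float)
    n, G = Y.shape
    batch = np.asarray(batch)
    if len(batch) != n:
        raise ValueError("batch labels not aligned with measures")
    labels = sorted(pd.unique(batch).tolist())
    B = len(labels)
    onehot = np.column_stack([(batch == b).astype(float) for b in labels])
    counts = onehot.sum(axis=0)
    if (counts < 2).any():
        bad = [labels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"batches with < 2 observations: {bad}")

    if covariates is not None:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("covariate design not aligned with measures")
    else:
        X = np.empty((n, 0))
    design = np.hstack([onehot, X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariates confounded with batch (design not full rank)")

    if B == 1:
        fit = CombatFit(
            feature_names=features,
            batch_labels=labels,
            alpha=Y.mean(axis=0),
            beta=np.zeros((X.shape[1], G)),
            sigma=Y.std(axis=0),
            gamma_star=np.zeros((1, G)),
            delta_star=np.ones((1, G)),
            gamma_bar=np.zeros(1),
            tau2=np.ones(1),
            lambda_prior=np.ones(1),
            theta_prior=np.ones(1),
            n_iter=0,
        )
        return NetworkMeasureTable(measures.data.copy(), list(measures.loading_columns)), fit

    # joint OLS of batch means and covariate effects
    coefs, *_ = np.linalg.lstsq(design, Y, rcond=None)
    batch_int = coefs[:B]                     # B x G per-batch intercepts
    beta = coefs[B:]                          # p x G
    alpha = (counts / n) @ batch_int          # size-weighted grand intercept
    stand_mean = alpha + X @ beta             # n x G
    resid = Y - design @ coefs
    sigma2 = (resid ** 2).mean(axis=0)
    sigma = np.sqrt(sigma2)
    if (sigma == 0).any():
        raise ValueError("zero pooled variance for some feature")

    Z = (Y - stand_mean) / sigma

    gamma_star = np.zeros((B, G))
    delta_star = np.zeros((B, G))
    gamma_bar = np.zeros(B)
    tau2 = np.zeros(B)
    lam_prior = np.zeros(B)
    theta_prior = np.zeros(B)
    total_iter = 0
    for i, b in enumerate(labels):
        zi = Z[batch == b]
        gamma_hat = zi.mean(axis=0)
        delta2_hat = zi.var(axis=0, ddof=1)
        gamma_bar[i] = gamma_hat.mean()
        tau2[i] = gamma_hat.var(ddof=1) if G > 1 else 1.0
        m = delta2_hat.mean()
        s2 = delta2_hat.var(ddof=1) if G > 1 else 1.0
        if s2 <= 0:
            s2 = 1e-8
        lam_prior[i] = (2 * s2 + m ** 2) / s2
        theta_prior[i] = (m * s2 + m ** 3) / s2
        if tau2[i] <= 0:
            tau2[i] = 1e-8
        g, d2, it = _eb_iterate(
            zi, gamma_hat, delta2_hat, gamma_bar[i], tau2[i],
            lam_prior[i], theta_prior[i],
        )
        gamma_star[i] = g
        delta_star[i] = np.sqrt(d2)
        total_iter = max(total_iter, it)

    Z_adj = Z.copy()
    for i, b in enumerate(labels):
        mask = batch == b
        Z_adj[mask] = (Z[mask] - gamma_star[i]) / delta_star[i]
    Y_adj = Z_adj * sigma + stand_mean

    out = measures.data.copy()
    out[features] = Y_adj
    fit = CombatFit(
        feature_names=features,
        batch_labels=labels,
        alpha=np.asarray(alpha),
        beta=beta,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        lambda_prior=lam_prior,
        theta_prior=theta_prior,
        n_iter=total_iter,
    )
    return NetworkMeasureTable(out, list(measures.loading_columns)), fit
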