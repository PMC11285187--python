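"""Spatial ICA network discovery, sign orientation and stability matching.

ICA is fit on the observation × region matrix of GM volumes: the recovered
independent sources are the per-observation network loadings ("a network
measure for each participant and each time point") and the mixing columns
are the spatial maps over regions.  Component signs are arbitrary, so each
network is oriented so that its loading correlates non-negatively with
whole-brain GM: after orientation a lower loading always means lower GM
volume.  Stability between two independent decompositions is assessed by
pairwise Pearson correlation of the spatial maps under an optimal one-to-one
assignment; matched pairs with |r| >= 0.8 are flagged consistent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from gmnet.cohort import CohortTable, RegionMismatchError

__all__ = ["ICADecomposition", "fit_ica", "orient_signs", "match_components",
           "CONSISTENCY_THRESHOLD"]

logger = logging.getLogger(__name__)

#: matched |r| at or above which two components are called the same network
CONSISTENCY_THRESHOLD = 0.8


@dataclass
class ICADecomposition:
    """A fitted spatial ICA model.

    ``maps`` (K × R) are the spatial networks; ``loadings`` (n_obs × K) the
    per-observation expression of each network.  ``mean_r``, ``whitening``
    (K × R) and ``unmixing`` (K × K) reproduce the fit:
    ``loadings = (X - mean_r) @ whitening.T @ unmixing.T`` up to the stored
    sign orientation.
    """

    K: int
    region_names: list
    mean_r: np.ndarray
    whitening: np.ndarray   # K x R PCA whitening matrix
    unmixing: np.ndarray    # K x K rotation applied to whitened data
    maps: np.ndarray        # K x R spatial maps (mixing rows)
    loadings: np.ndarray    # n_obs x K, sign-oriented
    orient_flags: np.ndarray  # K entries in {+1, -1}
    converged: bool
    iterations: int
    seed: int

    def project(self, X: np.ndarray) -> np.ndarray:
        """Loadings for new observations using the frozen fit (no re-estimation)."""
        X = np.asarray(X, dtype=float)
        raw = (X - self.mean_r) @ self.whitening.T @ self.unmixing.T
        return raw * self.orient_flags

    def to_json(self, path) -> None:
        d = {
            "K": self.K,
            "region_names": list(self.region_names),
            "mean_r": self.mean_r.tolist(),
            "whitening": self.whitening.tolist(),
            "unmixing": self.unmixing.tolist(),
            "maps": self.maps.tolist(),
            "orient_flags": self.orient_flags.tolist(),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "seed": int(self.seed),
            "convention": "observations-as-samples; maps are mixing rows",
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "ICADecomposition":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("convention", None)
        for key in ("mean_r", "whitening", "unmixing", "maps", "orient_flags"):
            d[key] = np.asarray(d[key], dtype=float)
        d["loadings"] = np.empty((0, d["K"]))
        return cls(**d)


def _as_matrix(data):
    if isinstance(data, CohortTable):
        return data.volumes(), list(data.region_names)
    X = np.asarray(data, dtype=float)
    return X, [f"r{i}" for i in range(X.shape[1])]


def fit_ica(
    data,
    K: int = 20,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> ICADecomposition:
    """Fit FastICA (logcosh contrast, symmetric updates, PCA whitening to K).

    ``data`` is a :class:`CohortTable` or an observation × region array of
    raw volumes.  Components are sign-oriented against whole-brain GM (the
    regional sum) before being returned; the decomposition is deterministic
    given ``seed``.  Non-convergence within ``max_iter`` is returned with
    ``converged=False`` and a logged warning rather than raised.
    """
    X, region_names = _as_matrix(data)
    n_obs, R = X.shape
    if K > min(n_obs, R):
        raise ValueError(f"K={K} exceeds min(n_obs={n_obs}, R={R})")
    if K < 1:
        raise ValueError("K must be >= 1")

    # constant regions carry no covariance signal and exact zeros break the
    # SVD sign convention downstream; fit on the varying regions only
    active = X.var(axis=0) > 0
    X_full, mean_full = X, X.mean(axis=0)
    if not active.all():
        logger.warning("excluding %d zero-variance regions from ICA", (~active).sum())
        if K > active.sum():
            raise ValueError(f"K={K} exceeds the {active.sum()} varying regions")
        X = X[:, active]

    ica = FastICA(
        n_components=K,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            loadings = ica.fit_transform(X)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    n_components=K, algorithm="parallel", fun="logcosh",
                    whiten="unit-variance", tol=tol, max_iter=max_iter,
                    random_state=seed,
                )
                loadings = ica.fit_transform(X)
            logger.warning("FastICA did not converge in %d iterations", max_iter)

    # scale so whitened = (X - mean) @ whitening.T has identity covariance
    # (1/n convention); the compensating factor keeps the product unchanged
    whitening = np.asarray(ica.whitening_) * np.sqrt(n_obs)   # K x R_active
    unmixing = np.asarray(ica._unmixing) / np.sqrt(n_obs)     # K x K rotation
    maps = np.asarray(ica.mixing_).T              # K x R_active
    mean_r = mean_full
    if not active.all():
        w = np.zeros((K, R))
        w[:, active] = whitening
        whitening = w
        m = np.zeros((K, R))
        m[:, active] = maps
        maps = m

    gm_total = X_full.sum(axis=1)
    loadings, maps, flags = orient_signs(loadings, maps, gm_total)
    return ICADecomposition(
        K=K,
        region_names=region_names,
        mean_r=mean_r,
        whitening=whitening,
        unmixing=unmixing,
        maps=maps,
        loadings=loadings,
        orient_flags=flags,
        converged=converged,
        iterations=int(ica.n_iter_),
        seed=seed,
    )


def orient_signs(loadings: np.ndarray, maps: np.ndarray, gm_total: np.ndarray):
    """Flip each component so its loading correlates non-negatively with GM.

    Negating a loading column and its map row together leaves the product
    ``loadings @ maps`` unchanged; only the reporting convention moves.
    Zero-variance loadings have undefined orientation and are left as-is
    with a warning.
    """
    loadings = np.array(loadings, dtype=float, copy=True)
    maps = np.array(maps, dtype=float, copy=True)
    gm_total = np.asarray(gm_total, dtype=float)
    K = maps.shape[0]
    flags = np.ones(K)
    gc = gm_total - gm_total.mean()
    gm_sd = gc.std()
    for k in range(K):
        lk = loadings[:, k]
        sd = lk.std()
        if sd == 0 or gm_sd == 0:
            logger.warning("component %d has zero-variance loading; sign left as-is", k)
            continue
        r = float((lk - lk.mean()) @ gc) / (len(lk) * sd * gm_sd)
        if r < 0:
            flags[k] = -1.0
            loadings[:, k] = -loadings[:, k]
            maps[k] = -maps[k]
    return loadings, maps, flags


def match_components(A: ICADecomposition, B: ICADecomposition):
    """Optimally pair the components of two decompositions by spatial correlation.

    Computes all K_A × K_B Pearson correlations between spatial maps and the
    one-to-one assignment maximizing the summed |r| (Hungarian algorithm).
    Returns a list of dicts ``{"k_a", "k_b", "r", "consistent"}`` where
    ``consistent`` means |r| >= 0.8.
    """
    if list(A.region_names) != list(B.region_names):
        raise RegionMismatchError("decompositions cover different region sets")
    MA = A.maps - A.maps.mean(axis=1, keepdims=True)
    MB = B.maps - B.maps.mean(axis=1, keepdims=True)
    MA = MA / np.linalg.norm(MA, axis=1, keepdims=True)
    MB = MB / np.linalg.norm(MB, axis=1, keepdims=True)
    corr = MA @ MB.T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    return [
        {
            "k_a": int(i),
            "k_b": int(j),
            "r": float(corr[i, j]),
            "consistent": bool(abs(corr[i, j]) >= CONSISTENCY_THRESHOLD),
        }
        for i, j in zip(rows, cols)
    ]
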