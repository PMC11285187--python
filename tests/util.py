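"""Shared test helpers: truth matching and hand-built mini cohorts."""

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from gmnet.cohort import CohortTable, NetworkMeasureTable


def corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between two map matrices."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    return A @ B.T


def match_to_truth(est_maps: np.ndarray, true_maps: np.ndarray):
    """Hungarian-match estimated to planted maps on |r|.

    Returns (component index per true network, signed r per true network).
    """
    C = corr_matrix(true_maps, est_maps)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(len(rows), dtype=int)
    r = np.empty(len(rows))
    for i, j in zip(rows, cols):
        perm[i] = j
        r[i] = C[i, j]
    return perm, r


def two_visit_cohort(delta_by_subject: np.ndarray, arms: np.ndarray, seed: int = 0):
    """Minimal 2-visit cohort + single-network measure table.

    Each subject's measure changes by the given delta between visit 0 and 1;
    useful for exercising first-to-last change statistics with full control.
    """
    rng = np.random.default_rng(seed)
    n = len(delta_by_subject)
    base = rng.normal(10.0, 1.0, n)
    rows = []
    for i in range(n):
        for v in (0, 1):
            rows.append({
                "subject_id": f"P{i:05d}", "trial_id": "t", "site_id": "s1",
                "phenotype": "RR", "arm": arms[i], "visit_index": v,
                "time_years": float(v), "age_baseline": 40.0, "sex": "F",
                "disease_duration": 5.0, "tiv": 1.4e6, "edss": 3.0,
                "gm_a": 5000.0 + rng.uniform(0.0, 100.0),
                "gm_b": 6000.0 + rng.uniform(0.0, 100.0),
            })
    cohort = CohortTable(pd.DataFrame(rows), ["gm_a", "gm_b"])
    meas = cohort.data[["subject_id", "visit_index"]].copy()
    vals = np.repeat(base, 2)
    vals[1::2] += np.asarray(delta_by_subject, dtype=float)
    meas["loading_1"] = vals
    meas["gm_total"] = cohort.data[["gm_a", "gm_b"]].sum(axis=1)
    return cohort, NetworkMeasureTable(meas, ["loading_1"])
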