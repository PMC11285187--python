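"""Treatment-effect detection and trial-planning sample sizes.

Treatment sensitivity of each network measure is tested with a mixed model
of the measure on time, arm and their interaction (plus baseline age, sex
and TIV), FDR-corrected across measures.  Effect sizes use each subject's
first-to-last-visit change: Cohen's d is the arm difference of the mean
change divided by the pooled change SD.  Per-arm sample sizes invert the
exact noncentral-t power function of the two-sided two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from gmnet.cohort import CohortTable, NetworkMeasureTable
from gmnet.stats import (
    AnalysisReport,
    apc_from_slope,
    bh_fdr,
    fit_lmm,
    merge_measures,
)

__all__ = [
    "TreatmentReport",
    "treatment_model",
    "first_last_effect_size",
    "sample_size_per_arm",
    "full_treatment_report",
]

logger = logging.getLogger(__name__)


@dataclass
class TreatmentReport:
    """Per-measure treatment findings.

    ``table`` columns: interaction beta/se/ci/p/q, per-arm annual percentage
    change; effect-size columns (delta_change, pooled_sd, cohens_d,
    n_per_arm) are filled by :func:`full_treatment_report`.
    """

    table: pd.DataFrame
    results: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def treatment_model(
    measures: NetworkMeasureTable,
    cohort: CohortTable,
    alpha: float = 0.05,
) -> TreatmentReport:
    """Time × arm mixed models per network measure and whole-brain GM."""
    df = merge_measures(measures, cohort)
    arms = set(df["arm"])
    if not {"treated", "comparator"} <= arms:
        raise ValueError("both treated and comparator arms are required")

    outcomes = [*measures.loading_columns, "gm_total"]
    cols = [np.ones(len(df)), df["time_years"], df["treated"],
            df["time_years"] * df["treated"]]
    terms = ["const", "time_years", "treated", "time:treated"]
    for c in ("age_baseline", "sex_M", "tiv"):
        if df[c].std() > 0:
            cols.append(df[c])
            terms.append(c)
    X = np.column_stack(cols)

    results, rows = {}, []
    for out in outcomes:
        res = fit_lmm(df[out], X, df["subject_id"], terms)
        results[out] = res
        t = res["time:treated"]
        slope_comp = res["time_years"]["beta"]
        slope_trt = slope_comp + t["beta"]
        sd = float(df[out].std())
        base_t = df.loc[(df["treated"] == 1) & (df["time_years"] == 0), out].mean()
        base_c = df.loc[(df["treated"] == 0) & (df["time_years"] == 0), out].mean()
        rows.append({
            "measure": out,
            "beta": t["beta"], "se": t["se"],
            "ci_lo": t["ci95"][0], "ci_hi": t["ci95"][1], "p": t["p"],
            "apc_treated": apc_from_slope(slope_trt, float(base_t), sd)["apc"],
            "apc_comparator": apc_from_slope(slope_comp, float(base_c), sd)["apc"],
        })
    table = pd.DataFrame(rows)
    q, rej = bh_fdr(table["p"].to_numpy(), alpha)
    table["q"] = q
    table["significant"] = rej
    return TreatmentReport(table=table, results=results, meta={"alpha": alpha})


def first_last_effect_size(
    measures: NetworkMeasureTable,
    cohort: CohortTable,
) -> pd.DataFrame:
    """Cohen's d of first-to-last-visit change between arms, per measure.

    Each subject contributes Δ = measure(last visit) − measure(first visit);
    d = (mean Δ_treated − mean Δ_comparator) / pooled SD of Δ.  Subjects with
    a single visit are excluded (count logged).
    """
    df = merge_measures(measures, cohort)
    outcomes = [*measures.loading_columns, "gm_total"]
    counts = df.groupby("subject_id")["visit_index"].count()
    single = counts[counts < 2].index
    if len(single):
        logger.info("excluding %d single-visit subjects from effect sizes", len(single))
    df = df[~df["subject_id"].isin(single)]
    if df.empty:
        raise ValueError("no subjects with >= 2 visits")

    df = df.sort_values(["subject_id", "visit_index"])
    first = df.groupby("subject_id").first()
    last = df.groupby("subject_id").last()
    arm = first["arm"]
    rows = []
    for out in outcomes:
        delta = last[out] - first[out]
        d_t = delta[arm == "treated"]
        d_c = delta[arm == "comparator"]
        if len(d_t) < 2 or len(d_c) < 2:
            raise ValueError("need >= 2 subjects with paired visits per arm")
        pooled = np.sqrt(
            ((len(d_t) - 1) * d_t.var(ddof=1) + (len(d_c) - 1) * d_c.var(ddof=1))
            / (len(d_t) + len(d_c) - 2)
        )
        if pooled == 0:
            raise ValueError(f"zero pooled change SD for {out}; d undefined")
        diff = float(d_t.mean() - d_c.mean())
        rows.append({
            "measure": out,
            "delta_change": diff,
            "pooled_sd": float(pooled),
            "cohens_d": diff / float(pooled),
            "n_treated": int(len(d_t)),
            "n_comparator": int(len(d_c)),
        })
    return pd.DataFrame(rows)


def _t_power(n: int, d: float, alpha: float) -> float:
    """Exact power of the two-sided two-sample t-test, n per arm."""
    df = 2 * n - 2
    nc = abs(d) * np.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_per_arm(
    cohens_d: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Smallest per-arm n whose two-sample t-test reaches the target power.

    Uses the exact noncentral-t power function (noncentrality d·√(n/2),
    df = 2n − 2), matching standard power software; symmetric in the sign
    of d.
    """
    if cohens_d == 0:
        raise ValueError("effect size 0: required sample size is unbounded")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    d = abs(cohens_d)
    n = 2
    while _t_power(n, d, alpha) < power:
        if n > 10_000_000:
            raise ValueError("required sample size exceeds 1e7 per arm")
        n *= 2
    lo, hi = max(2, n // 2), n   # power(hi) >= target
    while lo < hi:
        mid = (lo + hi) // 2
        if _t_power(mid, d, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def full_treatment_report(
    measures: NetworkMeasureTable,
    cohort: CohortTable,
    alpha: float = 0.05,
    power: float = 0.80,
) -> TreatmentReport:
    """Model, effect-size and sample-size columns combined per measure."""
    report = treatment_model(measures, cohort, alpha=alpha)
    es = first_last_effect_size(measures, cohort)
    table = report.table.merge(es, on="measure")
    table["n_per_arm"] = [
        sample_size_per_arm(d, alpha, power) if d != 0 else np.nan
        for d in table["cohens_d"]
    ]
    report.table = table
    report.meta.update({"power": power})
    return report
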