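"""Synthetic longitudinal cohorts with planted grey-matter network structure.

The generator emulates the long-format trial table the pipeline consumes:
``K`` latent networks, each a sparse non-negative spatial map over ``R``
regions; per-subject loading trajectories with phenotype-specific annual
slopes; an additive slope change under treatment for a subset of networks;
multiplicative per-site scanner gains; head-size (TIV) scaling; and EDSS
driven by a designated "clinical" subset of networks.  Every planted
quantity is recorded in :class:`GroundTruth` so downstream stages can be
validated against known truth.

Generative model for subject ``i``, network ``k``, region ``r`` at time ``t``
(years from baseline)::

    l_ik(t) = b_ik + (slope[phen_i][k] + treat_delta[k] * 1[arm=treated]) * t + eps
    v_ir(t) = tiv_i / ref_tiv * site_gain[site_i][r]
              * (mu_r + sum_k l_ik(t) * maps[k, r] + eta)
    edss_it = beta0 + sum_k clinical_weights[k] * l_ik(t)
              + beta_age * age_i + zeta   -> rounded to half points, clipped [0, 10]

Subject baselines ``b_ik`` are Laplace-distributed around phenotype-specific
means: the heavy tails make the latent sources identifiable by ICA, and the
phenotype means create baseline group differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from gmnet.cohort import CohortTable, PHENOTYPES

__all__ = ["SynthConfig", "GroundTruth", "make_ground_truth", "simulate_cohort"]


@dataclass
class SynthConfig:
    """Knobs of the planted generative model (defaults are the study conditions).

    Volumes are mm³ and times years throughout. Network loadings live on the
    same mm³ scale as volumes because each spatial map row sums to one.
    """

    n_regions: int = 60
    k_networks: int = 8
    support_min: int = 5          #: min regions per network map (>= 3)
    support_max: int = 10         #: max regions per network map (<= R/4)
    max_overlap: float = 0.5      #: fraction of the smaller support two maps may share
    mu_low: float = 6000.0        #: per-region baseline mean volume range (mm³)
    mu_high: float = 12000.0
    loading_mean_low: float = 2000.0   #: network-level mean loading range (mm³)
    loading_mean_high: float = 4000.0
    phenotype_shift_sd: float = 400.0  #: SD of phenotype offsets on baseline means
    sigma_baseline: float = 3000.0     #: between-subject loading SD (Laplace)
    sigma_loading: float = 150.0       #: within-subject visit-level loading noise SD
    sigma_region: float = 40.0         #: per-region residual volume noise SD (mm³)
    sigma_edss: float = 0.5            #: EDSS residual SD before rounding
    #: annual loading drift ranges per phenotype (mm³ of network volume / year);
    #: negative = atrophy, progressive phenotypes faster than RR
    slope_range: dict = field(
        default_factory=lambda: {
            "RR": (-30.0, -5.0),
            "SP": (-60.0, -25.0),
            "PP": (-55.0, -20.0),
        }
    )
    n_treatment_networks: int = 3      #: networks whose slope responds to treatment
    #: slope change under treatment (mm³/yr, slows atrophy); sized so the
    #: time x arm interaction has Wald z ~ 6 at the default application-cohort
    #: size (300 subjects/arm, 4 annual visits, visit noise 150)
    treat_delta_range: tuple = (30.0, 45.0)
    n_clinical_networks: int = 3       #: networks that drive EDSS
    clinical_weight_range: tuple = (0.5, 1.0)  #: EDSS shift (points) per baseline-SD of loading
    n_sites: int = 4
    site_gain_low: float = 0.98        #: multiplicative per-region scanner gain bounds
    site_gain_high: float = 1.02
    tiv_mean: float = 1.45e6           #: total intracranial volume (mm³)
    tiv_sd: float = 15e3
    edss_target_mean: float = 4.5
    edss_age_coef: float = 0.02        #: EDSS points per year of baseline age
    edss_missing: float = 0.05         #: fraction of visits with missing EDSS
    age_mean: float = 45.0
    age_sd: float = 10.0


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic cohort; consumed only by tests/validation."""

    K_true: int
    region_names: list
    maps_true: np.ndarray          # K x R, non-negative, rows sum to 1
    mu_region: np.ndarray          # R baseline mean volumes
    baseline_mean: dict            # phenotype -> K mean baseline loadings
    slope: dict                    # phenotype -> K annual drifts
    treat_delta: np.ndarray        # K additive slope changes under treatment
    treatment_networks: np.ndarray  # indices with treat_delta != 0
    clinical_weights: np.ndarray   # K EDSS weights (per mm³ of loading)
    clinical_networks: np.ndarray  # indices with nonzero EDSS weight
    sigma_baseline: float
    sigma_loading: float
    sigma_region: float
    sigma_edss: float
    site_gain: dict                # site label -> R multiplicative gains
    tiv_mean: float
    tiv_sd: float
    ref_tiv: float
    edss_intercept: float
    edss_age_coef: float
    edss_missing: float
    age_mean: float
    age_sd: float
    seed: int

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("maps_true", "mu_region", "treat_delta", "treatment_networks",
                    "clinical_weights", "clinical_networks"):
            d[key] = np.asarray(d[key]).tolist()
        d["baseline_mean"] = {p: np.asarray(v).tolist() for p, v in d["baseline_mean"].items()}
        d["slope"] = {p: np.asarray(v).tolist() for p, v in d["slope"].items()}
        d["site_gain"] = {s: np.asarray(v).tolist() for s, v in d["site_gain"].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["maps_true"] = np.asarray(d["maps_true"], dtype=float)
        d["mu_region"] = np.asarray(d["mu_region"], dtype=float)
        d["treat_delta"] = np.asarray(d["treat_delta"], dtype=float)
        d["treatment_networks"] = np.asarray(d["treatment_networks"], dtype=int)
        d["clinical_weights"] = np.asarray(d["clinical_weights"], dtype=float)
        d["clinical_networks"] = np.asarray(d["clinical_networks"], dtype=int)
        d["baseline_mean"] = {p: np.asarray(v, dtype=float) for p, v in d["baseline_mean"].items()}
        d["slope"] = {p: np.asarray(v, dtype=float) for p, v in d["slope"].items()}
        d["site_gain"] = {s: np.asarray(v, dtype=float) for s, v in d["site_gain"].items()}
        return cls(**d)


def _sample_supports(rng, K, R, smin, smax, max_overlap, max_tries=2000):
    """Rejection-sample K sparse supports with bounded pairwise overlap."""
    supports = []
    tries = 0
    while len(supports) < K:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "infeasible support constraints: could not place "
                f"{K} maps of size {smin}-{smax} on {R} regions with "
                f"overlap < {max_overlap}"
            )
        s = int(rng.integers(smin, smax + 1))
        cand = set(rng.choice(R, size=s, replace=False).tolist())
        ok = all(
            len(cand & prev) < max_overlap * min(len(cand), len(prev))
            for prev in supports
        )
        if ok:
            supports.append(cand)
    return [np.sort(np.fromiter(s, dtype=int)) for s in supports]


def make_ground_truth(config: SynthConfig | None = None, seed: int = 0) -> GroundTruth:
    """Draw a :class:`GroundTruth` deterministically from ``config`` and ``seed``."""
    cfg = config or SynthConfig()
    if cfg.k_networks < 1:
        raise ValueError("k_networks must be >= 1")
    if cfg.n_regions < 4 * cfg.k_networks:
        raise ValueError("need n_regions >= 4 * k_networks")
    if cfg.support_min < 3 or cfg.support_max > cfg.n_regions // 4:
        raise ValueError("support sizes must satisfy 3 <= s <= R/4")
    rng = np.random.default_rng(seed)
    K, R = cfg.k_networks, cfg.n_regions

    supports = _sample_supports(
        rng, K, R, cfg.support_min, cfg.support_max, cfg.max_overlap
    )
    maps = np.zeros((K, R))
    for k, sup in enumerate(supports):
        w = rng.dirichlet(np.full(len(sup), 2.0))
        maps[k, sup] = w

    mu_region = rng.uniform(cfg.mu_low, cfg.mu_high, size=R)
    base = rng.uniform(cfg.loading_mean_low, cfg.loading_mean_high, size=K)
    baseline_mean = {
        p: base + rng.normal(0.0, cfg.phenotype_shift_sd, size=K) for p in PHENOTYPES
    }
    slope = {
        p: rng.uniform(*cfg.slope_range[p], size=K) for p in PHENOTYPES
    }

    treat_delta = np.zeros(K)
    n_treat = min(cfg.n_treatment_networks, K)
    treat_idx = np.sort(rng.choice(K, size=n_treat, replace=False)) if n_treat else np.array([], int)
    if n_treat:
        treat_delta[treat_idx] = rng.uniform(*cfg.treat_delta_range, size=n_treat)

    clinical_weights = np.zeros(K)
    n_clin = min(cfg.n_clinical_networks, K)
    clin_idx = np.sort(rng.choice(K, size=n_clin, replace=False)) if n_clin else np.array([], int)
    if n_clin:
        # negative: losing network volume raises disability
        clinical_weights[clin_idx] = (
            -rng.uniform(*cfg.clinical_weight_range, size=n_clin) / cfg.sigma_baseline
        )

    site_gain = {
        f"site{s + 1}": rng.uniform(cfg.site_gain_low, cfg.site_gain_high, size=R)
        for s in range(cfg.n_sites)
    }

    # intercept chosen so the population mean EDSS sits near the target
    mean_loading = np.mean([baseline_mean[p] for p in PHENOTYPES], axis=0)
    intercept = (
        cfg.edss_target_mean
        - float(clinical_weights @ mean_loading)
        - cfg.edss_age_coef * cfg.age_mean
    )

    return GroundTruth(
        K_true=K,
        region_names=[f"gm_{i + 1:03d}" for i in range(R)],
        maps_true=maps,
        mu_region=mu_region,
        baseline_mean=baseline_mean,
        slope=slope,
        treat_delta=treat_delta,
        treatment_networks=treat_idx,
        clinical_weights=clinical_weights,
        clinical_networks=clin_idx,
        sigma_baseline=cfg.sigma_baseline,
        sigma_loading=cfg.sigma_loading,
        sigma_region=cfg.sigma_region,
        sigma_edss=cfg.sigma_edss,
        site_gain=site_gain,
        tiv_mean=cfg.tiv_mean,
        tiv_sd=cfg.tiv_sd,
        ref_tiv=cfg.tiv_mean,
        edss_intercept=intercept,
        edss_age_coef=cfg.edss_age_coef,
        edss_missing=cfg.edss_missing,
        age_mean=cfg.age_mean,
        age_sd=cfg.age_sd,
        seed=seed,
    )


def simulate_cohort(
    gt: GroundTruth,
    n_subjects: int = 100,
    visits: int = 4,
    visit_spacing_years: float = 1.0,
    seed: int = 0,
    phenotypes: tuple = PHENOTYPES,
    arms: tuple = ("treated", "comparator"),
    jitter: float = 0.0,
    trial_id: str = "synth",
    subject_prefix: str = "S",
    retry_cap: int = 10,
) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a longitudinal cohort from planted ground truth.

    ``n_subjects`` is the count per phenotype × arm cell (or a dict keyed by
    ``(phenotype, arm)``). Returns the validated :class:`CohortTable` and a
    frame of the latent per-visit network loadings (tests only — real data
    never exposes these).
    """
    rng = np.random.default_rng(seed)
    K, R = gt.K_true, len(gt.region_names)
    sites = sorted(gt.site_gain)
    gain = np.vstack([gt.site_gain[s] for s in sites])

    cells = [(p, a) for p in phenotypes for a in arms]
    if isinstance(n_subjects, dict):
        counts = {c: n_subjects[c] for c in cells}
    else:
        counts = {c: int(n_subjects) for c in cells}

    rows, latents = [], []
    sid = 0
    b_scale = gt.sigma_baseline / np.sqrt(2.0)  # Laplace scale for this SD
    for (phen, arm) in cells:
        for _ in range(counts[(phen, arm)]):
            sid += 1
            subj = f"{subject_prefix}{sid:05d}"
            site_i = int(rng.integers(len(sites)))
            tiv = float(rng.normal(gt.tiv_mean, gt.tiv_sd)) if gt.tiv_sd > 0 else gt.tiv_mean
            tiv = max(tiv, 0.5 * gt.tiv_mean)
            age = float(np.clip(rng.normal(gt.age_mean, gt.age_sd), 18.0, 80.0))
            sex = "M" if rng.random() < 0.45 else "F"
            duration = float(np.clip(rng.gamma(2.0, 3.0), 0.1, 40.0))
            b = gt.baseline_mean[phen] + rng.laplace(0.0, b_scale, size=K)
            drift = gt.slope[phen] + (gt.treat_delta if arm == "treated" else 0.0)

            times = np.arange(visits) * visit_spacing_years
            if jitter > 0 and visits > 1:
                times = times + np.concatenate(
                    [[0.0], rng.uniform(-jitter, jitter, size=visits - 1)]
                )
                times = np.maximum.accumulate(times + 1e-9 * np.arange(visits))

            for v in range(visits):
                t = float(times[v])
                eps = rng.normal(0.0, gt.sigma_loading, size=K) if gt.sigma_loading > 0 else 0.0
                l = b + drift * t + eps
                signal = gt.mu_region + l @ gt.maps_true
                vols = None
                for _ in range(retry_cap):
                    eta = rng.normal(0.0, gt.sigma_region, size=R) if gt.sigma_region > 0 else 0.0
                    cand = tiv / gt.ref_tiv * gain[site_i] * (signal + eta)
                    if (cand > 0).all():
                        vols = cand
                        break
                if vols is None:
                    raise RuntimeError(
                        f"non-positive volumes persisted for subject {subj} after "
                        f"{retry_cap} noise resamples"
                    )
                zeta = rng.normal(0.0, gt.sigma_edss)
                edss = (
                    gt.edss_intercept
                    + float(gt.clinical_weights @ l)
                    + gt.edss_age_coef * age
                    + zeta
                )
                edss = float(np.clip(np.round(edss * 2) / 2, 0.0, 10.0))
                if rng.random() < gt.edss_missing:
                    edss = np.nan
                row = {
                    "subject_id": subj,
                    "trial_id": trial_id,
                    "site_id": sites[site_i],
                    "phenotype": phen,
                    "arm": arm,
                    "visit_index": v,
                    "time_years": t,
                    "age_baseline": age,
                    "sex": sex,
                    "disease_duration": duration,
                    "tiv": tiv,
                    "edss": edss,
                }
                row.update({name: vols[r] for r, name in enumerate(gt.region_names)})
                rows.append(row)
                lat = {"subject_id": subj, "visit_index": v, "time_years": t,
                       "phenotype": phen, "arm": arm}
                lat.update({f"l_{k + 1}": l[k] for k in range(K)})
                latents.append(lat)

    table = CohortTable(pd.DataFrame(rows), list(gt.region_names))
    return table, pd.DataFrame(latents)
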