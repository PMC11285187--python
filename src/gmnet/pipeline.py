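"""End-to-end workflow orchestration with seeds, logging and provenance.

Stage order mirrors the study design: simulate (or load) a training and an
application cohort → discover networks by ICA on the training cohort →
train the Lasso surrogate on a 70/30 subject split → apply the frozen
surrogate to the application cohort → harmonize measures across sites →
run the statistical analyses (phenotype trajectories, EDSS associations,
stepwise selection, treatment effects and sample sizes).  Training-cohort
artifacts are never refit on application data; every JSON artifact carries
the tool version and a hash of the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

import gmnet
from gmnet.cohort import read_cohort, write_cohort
from gmnet.harmonize import combat_fit_transform
from gmnet.ica import fit_ica, match_components
from gmnet.stats import (
    edss_association,
    phenotype_trajectories,
    stepwise_selection,
    subject_level_edss,
)
from gmnet.surrogate import apply_surrogate, train_surrogate
from gmnet.synth import SynthConfig, make_ground_truth, simulate_cohort
from gmnet.trial import full_treatment_report

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "k_networks": 8,
    "n_regions": 60,
    "n_subjects_per_cell": 100,
    "visits": 4,
    "visit_spacing_years": 1.0,
    "split_fraction": 0.70,
    "cv_folds": 5,
    "ica_max_iter": 500,
    "alpha": 0.05,
    "power": 0.80,
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def provenance(config: dict) -> dict:
    return {"tool": "gmnet", "version": gmnet.__version__,
            "config_hash": config_hash(config)}


def _seeds(global_seed: int) -> dict:
    """Derive per-stage seeds deterministically from the global seed."""
    ss = np.random.SeedSequence(global_seed)
    names = ["ground_truth", "train_cohort", "app_cohort", "ica_train",
             "ica_app", "surrogate_split"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: dict | None = None, out_dir="gmnet_run") -> dict:
    """Execute the full synthetic-cohort workflow; returns artifact paths.

    A stage failure aborts with the stage name; artifacts already written
    remain valid on disk.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(cfg["seed"])
    prov = provenance(cfg)
    artifacts: dict = {}
    stage = "configure"
    try:
        stage = "simulate"
        synth_cfg = SynthConfig(
            n_regions=cfg["n_regions"], k_networks=cfg["k_networks"]
        )
        gt = make_ground_truth(synth_cfg, seed=seeds["ground_truth"])
        train_tab, _ = simulate_cohort(
            gt, n_subjects=cfg["n_subjects_per_cell"], visits=cfg["visits"],
            visit_spacing_years=cfg["visit_spacing_years"],
            seed=seeds["train_cohort"], trial_id="train", subject_prefix="T",
        )
        app_tab, _ = simulate_cohort(
            gt, n_subjects=cfg["n_subjects_per_cell"], visits=cfg["visits"],
            visit_spacing_years=cfg["visit_spacing_years"],
            seed=seeds["app_cohort"], trial_id="app", subject_prefix="A",
        )
        gt.to_json(out / "ground_truth.json")
        write_cohort(train_tab, out / "training_cohort.csv")
        write_cohort(app_tab, out / "application_cohort.csv")
        artifacts.update(
            ground_truth=out / "ground_truth.json",
            training_cohort=out / "training_cohort.csv",
            application_cohort=out / "application_cohort.csv",
        )

        stage = "discover"
        ica = fit_ica(train_tab, K=cfg["k_networks"], seed=seeds["ica_train"],
                      max_iter=cfg["ica_max_iter"])
        ica.to_json(out / "ica_model.json")
        artifacts["ica_model"] = out / "ica_model.json"

        stage = "stability"
        ica_app = fit_ica(app_tab, K=cfg["k_networks"], seed=seeds["ica_app"],
                          max_iter=cfg["ica_max_iter"])
        matches = match_components(ica, ica_app)
        with open(out / "stability.json", "w") as fh:
            json.dump({"provenance": prov, "matches": matches}, fh, indent=1)
        artifacts["stability"] = out / "stability.json"

        stage = "train-surrogate"
        model = train_surrogate(
            train_tab, ica, cv_folds=cfg["cv_folds"],
            fraction=cfg["split_fraction"], seed=seeds["surrogate_split"],
        )
        model.to_json(out / "surrogate.json")
        artifacts["surrogate"] = out / "surrogate.json"

        stage = "apply"
        meas_app = apply_surrogate(model, app_tab)
        meas_train = apply_surrogate(model, train_tab)
        meas_app.data.to_csv(out / "measures_application.csv", index=False)
        meas_train.data.to_csv(out / "measures_training.csv", index=False)
        artifacts["measures_application"] = out / "measures_application.csv"
        artifacts["measures_training"] = out / "measures_training.csv"

        stage = "harmonize"
        harm_train, _ = combat_fit_transform(
            meas_train, train_tab.data["site_id"].to_numpy(),
            covariates=np.column_stack([
                train_tab.data["age_baseline"],
                (train_tab.data["sex"] == "M").astype(float),
                train_tab.data["time_years"],
            ]),
        )
        harm_app, _ = combat_fit_transform(
            meas_app, app_tab.data["site_id"].to_numpy(),
            covariates=np.column_stack([
                app_tab.data["age_baseline"],
                (app_tab.data["sex"] == "M").astype(float),
                app_tab.data["time_years"],
            ]),
        )
        harm_train.data.to_csv(out / "measures_training_harmonized.csv", index=False)
        harm_app.data.to_csv(out / "measures_application_harmonized.csv", index=False)
        artifacts["measures_training_harmonized"] = out / "measures_training_harmonized.csv"
        artifacts["measures_application_harmonized"] = out / "measures_application_harmonized.csv"

        stage = "analyze-phenotype"
        phen = phenotype_trajectories(harm_train, train_tab, alpha=cfg["alpha"])
        phen.table.assign(**{"provenance": prov["config_hash"]}).to_csv(
            out / "phenotype_report.csv", index=False)
        artifacts["phenotype_report"] = out / "phenotype_report.csv"

        stage = "analyze-edss"
        edss = edss_association(harm_train, train_tab, alpha=cfg["alpha"])
        edss.table.assign(**{"provenance": prov["config_hash"]}).to_csv(
            out / "edss_report.csv", index=False)
        artifacts["edss_report"] = out / "edss_report.csv"

        stage = "analyze-stepwise"
        sig = edss.table.query("family == 'progression' and significant")["measure"]
        subj = subject_level_edss(train_tab)
        base_meas = harm_train.data.loc[
            train_tab.data["time_years"] == 0,
            ["subject_id", *harm_train.loading_columns, "gm_total"],
        ]
        sw_df = subj.merge(base_meas, on="subject_id")
        forced = ["age_baseline", "sex_M", "disease_duration", "treated", "tiv", "n_visits"]
        step = stepwise_selection(
            sw_df.dropna(subset=["edss_slope"]), "edss_slope",
            candidates=[m for m in sig if m in sw_df.columns], forced=forced,
        )
        with open(out / "stepwise_report.json", "w") as fh:
            json.dump({"provenance": prov, **step}, fh, indent=1)
        artifacts["stepwise_report"] = out / "stepwise_report.json"

        stage = "analyze-treatment"
        trt = full_treatment_report(harm_app, app_tab, alpha=cfg["alpha"],
                                    power=cfg["power"])
        trt.table.assign(**{"provenance": prov["config_hash"]}).to_csv(
            out / "treatment_report.csv", index=False)
        artifacts["treatment_report"] = out / "treatment_report.csv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {"provenance": prov, "config": cfg,
             "artifacts": {k: str(v) for k, v in artifacts.items()}},
            fh, indent=1,
        )
    artifacts["manifest"] = out / "run_manifest.json"
    return {k: str(v) for k, v in artifacts.items()}
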