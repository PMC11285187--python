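"""Cohort data model: long-format subject-visit tables of regional GM volumes.

A :class:`CohortTable` holds one row per subject-visit with the clinical
covariates used throughout the pipeline (phenotype, treatment arm, visit time
in years from baseline, baseline age, sex, disease duration, total
intracranial volume, EDSS) and ``R`` regional grey-matter volumes in mm³.
All downstream stages (ICA, surrogate scoring, harmonization, statistics)
consume these types; validation happens once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPES = ("RR", "SP", "PP")
ARMS = ("treated", "comparator", "none")
SEXES = ("M", "F")

#: Non-region columns every cohort file must provide.
REQUIRED_COLUMNS = (
    "subject_id",
    "trial_id",
    "site_id",
    "phenotype",
    "arm",
    "visit_index",
    "time_years",
    "age_baseline",
    "sex",
    "disease_duration",
    "tiv",
    "edss",
)

DEFAULT_REGION_PREFIX = "gm_"


class CohortValidationError(ValueError):
    """Base class for cohort validation failures."""


class MissingColumnError(CohortValidationError):
    pass


class DuplicateVisitError(CohortValidationError):
    pass


class BaselineMissingError(CohortValidationError):
    pass


class NonMonotoneTimeError(CohortValidationError):
    pass


class NegativeVolumeError(CohortValidationError):
    pass


class InconstantCovariateError(CohortValidationError):
    pass


class RegionMismatchError(CohortValidationError):
    """Region names/order differ between a fitted model and new data."""


def _fmt_rows(rows) -> str:
    rows = list(rows)
    shown = ", ".join(map(str, rows[:10]))
    if len(rows) > 10:
        shown += f", ... ({len(rows)} total)"
    return shown


@dataclass
class CohortTable:
    """Validated long-format cohort: one row per subject-visit.

    Parameters
    ----------
    data
        Frame with :data:`REQUIRED_COLUMNS` plus one column per region.
    region_names
        Region column labels, in order; identical across all rows.
    """

    data: pd.DataFrame
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()
        self.data = (
            self.data.sort_values(["subject_id", "visit_index"])
            .reset_index(drop=True)
        )

    # -- accessors ---------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def volumes(self) -> np.ndarray:
        """Observation × region matrix of GM volumes (mm³)."""
        return self.data[self.region_names].to_numpy(dtype=float)

    def subset_subjects(self, subject_ids) -> "CohortTable":
        keep = self.data["subject_id"].isin(set(subject_ids))
        return CohortTable(self.data.loc[keep].copy(), list(self.region_names))

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise MissingColumnError(f"missing required columns: {missing}")
        if not self.region_names:
            raise MissingColumnError("no region columns identified")
        absent = [r for r in self.region_names if r not in df.columns]
        if absent:
            raise MissingColumnError(f"region columns absent from data: {absent}")
        if len(df) == 0:
            raise CohortValidationError("cohort table has no rows")

        dup = df.duplicated(subset=["subject_id", "visit_index"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["subject_id", "visit_index"]].apply(tuple, axis=1)
            raise DuplicateVisitError(
                f"duplicate (subject_id, visit_index): {_fmt_rows(keys.unique())}"
            )

        by_subj = df.groupby("subject_id", sort=False)
        no_baseline = [s for s, g in by_subj if not (g["time_years"] == 0).any()]
        if no_baseline:
            raise BaselineMissingError(
                f"subjects without a time_years == 0 row: {_fmt_rows(no_baseline)}"
            )
        bad_time = [
            s
            for s, g in by_subj
            if not g.sort_values("visit_index")["time_years"].is_monotonic_increasing
            or g.sort_values("visit_index")["time_years"].duplicated().any()
        ]
        if bad_time:
            raise NonMonotoneTimeError(
                "time_years not strictly increasing with visit_index for "
                f"subjects: {_fmt_rows(bad_time)}"
            )

        for col in ("phenotype", "arm", "sex", "age_baseline", "disease_duration"):
            varying = [s for s, g in by_subj if g[col].nunique(dropna=False) > 1]
            if varying:
                raise InconstantCovariateError(
                    f"{col} varies within subjects: {_fmt_rows(varying)}"
                )

        vols = df[self.region_names].to_numpy(dtype=float)
        if np.isnan(vols).any():
            rows = df.index[np.isnan(vols).any(axis=1)]
            raise NegativeVolumeError(f"NaN region volumes at rows: {_fmt_rows(rows)}")
        if (vols < 0).any():
            rows = df.index[(vols < 0).any(axis=1)]
            raise NegativeVolumeError(
                f"negative region volumes at rows: {_fmt_rows(rows)}"
            )
        if (df["tiv"] <= 0).any():
            rows = df.index[df["tiv"] <= 0]
            raise CohortValidationError(f"non-positive TIV at rows: {_fmt_rows(rows)}")

        bad_phen = set(df["phenotype"].unique()) - set(PHENOTYPES)
        if bad_phen:
            raise CohortValidationError(f"unknown phenotype labels: {bad_phen}")
        bad_arm = set(df["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise CohortValidationError(f"unknown arm labels: {bad_arm}")
        bad_sex = set(df["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise CohortValidationError(f"unknown sex labels: {bad_sex}")

        edss = df["edss"].dropna()
        if ((edss < 0) | (edss > 10)).any() or ((edss * 2) % 1 != 0).any():
            raise CohortValidationError(
                "EDSS must lie in [0, 10] in half-point steps where present"
            )


@dataclass
class NetworkMeasureTable:
    """Per-visit network measures: one loading per network plus whole-brain GM.

    Row set is identical (same order) to the source :class:`CohortTable`;
    ``loading_k`` columns are sign-oriented so that lower values mean lower GM
    volume in that network. Columns may additionally be z-scored against a
    reference cohort.
    """

    data: pd.DataFrame  # subject_id, visit_index + loading columns + gm_total
    loading_columns: list[str]

    @property
    def n_networks(self) -> int:
        return len(self.loading_columns)

    def loadings(self) -> np.ndarray:
        return self.data[self.loading_columns].to_numpy(dtype=float)

    def zscored(self, reference: "NetworkMeasureTable | None" = None) -> "NetworkMeasureTable":
        """Z-score loading columns (and gm_total) against ``reference`` (default: self)."""
        ref = reference if reference is not None else self
        out = self.data.copy()
        for col in [*self.loading_columns, "gm_total"]:
            mu = ref.data[col].mean()
            sd = ref.data[col].std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero variance in reference column {col!r}")
            out[col] = (self.data[col] - mu) / sd
        return NetworkMeasureTable(out, list(self.loading_columns))


def read_cohort(
    path, region_prefix: str = DEFAULT_REGION_PREFIX
) -> CohortTable:
    """Read and validate a cohort CSV.

    Region columns are identified by ``region_prefix``; all validation errors
    name the offending rows/subjects. Rows come back sorted by
    (subject_id, visit_index).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str, "site_id": str})
    region_names = [c for c in df.columns if c.startswith(region_prefix)]
    return CohortTable(df, region_names)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV; ``read_cohort`` of the result reproduces the table.

    Comma-separated, UTF-8, '.' decimal; missing EDSS as empty field.
    """
    cols = [*REQUIRED_COLUMNS, *table.region_names]
    table.data[cols].to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def whole_brain_gm(table: CohortTable) -> pd.Series:
    """Whole-brain GM per row, defined as the sum of regional GM volumes."""
    total = table.data[table.region_names].sum(axis=1)
    total.name = "gm_total"
    return total


def measures_from_loadings(
    table: CohortTable, loadings: np.ndarray, prefix: str = "loading_"
) -> NetworkMeasureTable:
    """Assemble a NetworkMeasureTable from a loading matrix aligned to ``table``."""
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape[0] != table.n_obs:
        raise ValueError("loadings row count does not match cohort")
    cols = [f"{prefix}{k + 1}" for k in range(loadings.shape[1])]
    df = table.data[["subject_id", "visit_index"]].copy()
    for j, c in enumerate(cols):
        df[c] = loadings[:, j]
    df["gm_total"] = whole_brain_gm(table).to_numpy()
    return NetworkMeasureTable(df, cols)
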