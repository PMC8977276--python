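"""Cohort tables, marker annotations, and categorical recodings.

A cohort is one row per patient: overall-survival time in months, an
all-cause death indicator, clinicopathological covariates (T/N stage,
EMVI, UICC stage, differentiation grade, age group, tumour site, MMR
status — any subset), and a matrix of per-marker ordinal immunostaining
scores in which missing cores stay missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stats import as_survival


class CohortValidationError(ValueError):
    pass


#: default vocabulary for pathological covariates; unknown levels are
#: rejected rather than silently coerced.
DEFAULT_COVARIATE_LEVELS: dict[str, list[str]] = {
    "t_stage": ["T1", "T2", "T3", "T4"],
    "n_stage": ["N0", "N1", "N2"],
    "emvi": ["V0", "V1"],
    "differentiation": ["G1", "G2", "G3"],
    "uicc_stage": ["I", "II", "III"],
}


@dataclass
class MarkerAnnotation:
    """Biological/clinical metadata for one marker."""

    marker: str
    direction: str = "unknown"            # higher_better | higher_worse | unknown
    subsets: list[str] = field(default_factory=list)
    scoring: str = "semi_quantitative"    # or quantitative

    def __post_init__(self):
        if self.direction not in ("higher_better", "higher_worse", "unknown"):
            raise CohortValidationError(f"bad direction {self.direction!r} for {self.marker}")
        if self.scoring not in ("semi_quantitative", "quantitative"):
            raise CohortValidationError(f"bad scoring {self.scoring!r} for {self.marker}")


@dataclass
class Cohort:
    """Patient cohort: outcome, clinical covariates and marker scores.

    ``markers`` keeps missing scores as NaN; nothing is imputed at I/O
    time.  All three frames share the patient-id index.
    """

    patient_id: pd.Index
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self):
        n = len(self.patient_id)
        if self.patient_id.has_duplicates:
            dup = self.patient_id[self.patient_id.duplicated()].tolist()
            raise CohortValidationError(f"duplicate patient ids: {dup}")
        time = np.asarray(self.time, dtype=float)
        if time.shape[0] != n or np.any(~np.isfinite(time)) or np.any(time <= 0):
            bad = self.patient_id[~(np.isfinite(time) & (time > 0))].tolist()
            raise CohortValidationError(f"missing/non-positive survival time for patients {bad}")
        event = np.asarray(self.event, dtype=float)
        if event.shape[0] != n or not np.all(np.isin(event, (0.0, 1.0))):
            bad = self.patient_id[~np.isin(event, (0.0, 1.0))].tolist()
            raise CohortValidationError(f"event indicator not 0/1 for patients {bad}")
        if self.markers.shape[0] != n:
            raise CohortValidationError("marker matrix row count differs from patient count")
        if self.markers.columns.has_duplicates:
            raise CohortValidationError("duplicate marker names")
        self.time = time
        self.event = event.astype(int)

    @property
    def n_patients(self) -> int:
        return len(self.patient_id)

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers.columns)

    def survival(self) -> np.ndarray:
        """Structured (event, time) outcome array for the estimators."""
        return as_survival(self.time, self.event)

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            patient_id=self.patient_id[mask],
            time=self.time[mask],
            event=self.event[mask],
            covariates=self.covariates.loc[mask].copy(),
            markers=self.markers.loc[mask].copy(),
        )


def _load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_schema(path: str | Path) -> dict:
    """Read a column-mapping / annotation config (YAML or JSON)."""
    cfg = _load_config(path)
    if "time" not in cfg or "event" not in cfg:
        raise CohortValidationError("schema must name the time and event columns")
    return cfg


def read_annotations(source: str | Path | dict) -> dict[str, MarkerAnnotation]:
    """Load marker annotations from a YAML/JSON mapping marker -> fields."""
    raw = source if isinstance(source, dict) else _load_config(source)
    out = {}
    for marker, fields_ in raw.items():
        fields_ = dict(fields_ or {})
        out[marker] = MarkerAnnotation(marker=marker, **fields_)
    return out


def read_cohort(path: str | Path, schema: dict | str | Path) -> Cohort:
    """Read a delimited cohort table and validate it against a schema.

    ``schema`` maps roles to column names: ``id`` (optional), ``time``,
    ``event``, ``covariates`` (list), ``markers`` (list).  Missing marker
    cells (empty or "NA") are preserved as NaN.  Clinical covariate
    levels are checked against ``covariate_levels`` when the schema
    declares them (defaults cover T/N stage, EMVI, grade, UICC).
    """
    if not isinstance(schema, dict):
        schema = read_schema(schema)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype={schema.get("id", ""): str})

    id_col = schema.get("id")
    if id_col is not None:
        ids = pd.Index(df[id_col].astype(str), name="patient_id")
    else:
        ids = pd.Index([str(i) for i in range(len(df))], name="patient_id")

    for role in ("time", "event"):
        col = schema[role]
        if col not in df.columns:
            raise CohortValidationError(f"schema column {col!r} ({role}) not in file")
        missing = df[col].isna()
        if missing.any():
            raise CohortValidationError(
                f"missing {role} for patients {ids[missing.to_numpy()].tolist()}"
            )

    cov_cols = list(schema.get("covariates", []))
    marker_cols = list(schema.get("markers", []))
    for col in cov_cols + marker_cols:
        if col not in df.columns:
            raise CohortValidationError(f"schema column {col!r} not in file")

    covariates = df[cov_cols].copy()
    covariates.index = ids
    levels = {**DEFAULT_COVARIATE_LEVELS, **schema.get("covariate_levels", {})}
    for col in cov_cols:
        if col in levels:
            seen = set(covariates[col].dropna().astype(str))
            unknown = seen - set(map(str, levels[col]))
            if unknown:
                raise CohortValidationError(
                    f"unknown level(s) {sorted(unknown)} for covariate {col!r}; "
                    f"expected {levels[col]}"
                )

    markers = df[marker_cols].apply(pd.to_numeric, errors="raise")
    markers.index = ids
    return Cohort(
        patient_id=ids,
        time=df[schema["time"]].to_numpy(dtype=float),
        event=df[schema["event"]].to_numpy(),
        covariates=covariates,
        markers=markers,
    )


def write_cohort(cohort: Cohort, path: str | Path, schema: dict | None = None) -> dict:
    """Write a cohort back to delimited text in normalized column order.

    Returns the schema describing the written file, so that
    ``read_cohort(path, write_cohort(c, path))`` is a fixed point.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    out = pd.DataFrame(index=cohort.patient_id)
    out["time"] = cohort.time
    out["event"] = cohort.event
    for col in cohort.covariates.columns:
        out[col] = cohort.covariates[col].to_numpy()
    for col in cohort.markers.columns:
        out[col] = cohort.markers[col].to_numpy()
    out.reset_index().to_csv(path, sep=sep, index=False, na_rep="NA")
    return {
        "id": "patient_id",
        "time": "time",
        "event": "event",
        "covariates": list(cohort.covariates.columns),
        "markers": list(cohort.markers.columns),
    }


def quartile_bin(values) -> np.ndarray:
    """Bin a numeric vector into four ordinal categories at its quartiles.

    Cutpoints are the 25th/50th/75th percentiles (linear interpolation
    between order statistics); intervals are right-closed, so a value
    equal to a cutpoint falls in the lower category.  Missing values stay
    missing.  This reproduces the recoding used to align continuous
    expression values with 4-level immunostaining scores.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise CohortValidationError("quartile binning needs >= 4 non-missing values")
    if np.all(finite == finite[0]):
        raise CohortValidationError("degenerate: no quartile cutpoints")
    cuts = np.quantile(finite, [0.25, 0.50, 0.75])
    out = np.full(values.shape, np.nan)
    ok = np.isfinite(values)
    # right-closed: category = 1 + #{cutpoints strictly below the value}
    out[ok] = 1 + np.sum(values[ok, None] > cuts[None, :], axis=1)
    return out


def classify_path_risk(covariates: pd.DataFrame) -> pd.Series:
    """Binary pathological risk classification.

    Low risk iff T stage in {T1, T2, T3} and grade in {G1, G2} and no
    extramural venous invasion (V0) and node-negative (N0); anything else
    (pT4 or G3 or V1 or N1/N2) is high risk.  Patients missing any of
    the four fields get a missing classification.
    """
    required = ["t_stage", "differentiation", "emvi", "n_stage"]
    for col in required:
        if col not in covariates.columns:
            raise CohortValidationError(f"pathological risk needs covariate {col!r}")
    sub = covariates[required].astype("string")
    complete = sub.notna().all(axis=1)
    low = (
        sub["t_stage"].isin(["T1", "T2", "T3"])
        & sub["differentiation"].isin(["G1", "G2"])
        & (sub["emvi"] == "V0")
        & (sub["n_stage"] == "N0")
    )
    out = pd.Series(pd.NA, index=covariates.index, dtype="string", name="path_risk")
    out[complete & low] = "low"
    out[complete & ~low] = "high"
    return out
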