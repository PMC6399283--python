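"""Cohort table I/O, validation and result serialisation.

Coding conventions enforced here: categorical variables are 0/1
(absence/presence), sex is male = 0 / female = 1, and the five risk
factors (sex, age, bmi, htn, fhdm) plus the diabetes outcome ``dm`` must
be complete — rows missing any of them are removed and counted.  An age
window (default 40-70 years, the discovery cohort's range) filters rows,
and participants first diagnosed before age 20 are excluded to rule out
type 1 diabetes.  Follow-up and biomarker columns are optional and may
contain missing values; downstream operations handle them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sex", "age", "bmi", "htn", "fhdm", "dm")
BINARY_COLUMNS = ("sex", "htn", "fhdm", "dm")
OPTIONAL_COLUMNS = (
    "participant_id",
    "followup_months",
    "event",
    "fg",
    "tchol",
    "tg",
    "hdl",
    "prior_dx",
    "dx_age",
    "true_cluster",
)


@dataclass
class ValidationReport:
    """Row accounting of cohort validation; counts are conserved."""

    n_input: int
    n_removed_missing: int = 0
    n_removed_age: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_missing - self.n_removed_age


@dataclass
class CohortTable:
    """One row per participant; columns follow the study coding."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def risk_factors(self) -> pd.DataFrame:
        return self.df[["sex", "age", "bmi", "htn", "fhdm"]]


def validate_cohort(
    df: pd.DataFrame,
    age_window: tuple[float, float] | None = (40.0, 70.0),
    min_dx_age: float | None = 20.0,
) -> tuple[CohortTable, ValidationReport]:
    """Apply the study exclusions and coding checks to a raw table.

    Rows missing any risk factor or the outcome are removed; rows outside
    the age window are removed; when a diagnosis-age column ``dx_age`` is
    present, participants diagnosed before ``min_dx_age`` are removed
    (counted with the age exclusions).  Binary columns must be 0/1.
    """
    report = ValidationReport(n_input=len(df))
    df = df.copy()
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"unmapped required column(s): {missing_cols}")

    complete = df[list(REQUIRED_COLUMNS)].notna().all(axis=1)
    report.n_removed_missing = int((~complete).sum())
    if report.n_removed_missing:
        report.messages.append(
            f"removed {report.n_removed_missing} rows with missing risk factors"
        )
    df = df[complete]

    keep = pd.Series(True, index=df.index)
    if age_window is not None:
        lo, hi = age_window
        keep &= df["age"].between(lo, hi)
    if min_dx_age is not None and "dx_age" in df.columns:
        keep &= ~(df["dx_age"].notna() & (df["dx_age"] < min_dx_age))
    report.n_removed_age = int((~keep).sum())
    if report.n_removed_age:
        report.messages.append(
            f"removed {report.n_removed_age} rows outside the age window "
            "or diagnosed before the minimum diagnosis age"
        )
    df = df[keep].reset_index(drop=True)

    for col in BINARY_COLUMNS:
        values = df[col].to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"non-binary value in binary column {col!r}")
        df[col] = df[col].astype(int)
    if "event" in df.columns:
        bad = (df["event"] == 1) & ~(df["followup_months"] > 0)
        if bad.any():
            raise ValueError("event=1 requires followup_months > 0")
    if "participant_id" not in df.columns:
        df.insert(0, "participant_id", [f"P{i:06d}" for i in range(len(df))])
    df["participant_id"] = df["participant_id"].astype(str)
    return CohortTable(df), report


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    value_maps: Mapping[str, Mapping] | None = None,
    age_window: tuple[float, float] | None = (40.0, 70.0),
    min_dx_age: float | None = 20.0,
    sep: str | None = None,
) -> tuple[CohortTable, ValidationReport]:
    """Read a cohort CSV/TSV, recode columns and apply the validation rules.

    Parameters
    ----------
    schema : mapping of file column name -> canonical column name.
    value_maps : per-canonical-column value recodes, e.g.
        ``{"sex": {"M": 0, "F": 1}}``.
    sep : field separator; inferred from the extension when None.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns=dict(schema))
    if value_maps:
        for col, mapping in value_maps.items():
            if col in df.columns:
                df[col] = df[col].map(mapping).astype(float)
    return validate_cohort(df, age_window=age_window, min_dx_age=min_dx_age)


# ---------------------------------------------------------------------------
# diabetes / hypertension derivation from raw measurements

MMOL_PER_MGDL_GLUCOSE = 1.0 / 18.0


def derive_dm(
    df: pd.DataFrame,
    glucose_units: str = "mmol/L",
    fg_col: str = "fg",
    ogtt_col: str | None = "ogtt2h",
    hba1c_col: str | None = "hba1c",
    history_col: str | None = "prior_dx",
) -> pd.Series:
    """Diabetes status from diagnostic criteria and history.

    Positive when fasting glucose >= 7.0 mmol/L (126 mg/dL), 2-h OGTT
    glucose >= 11.1 mmol/L (200 mg/dL), HbA1c >= 6.5%, or a prior
    diagnosis/treatment history.  ``glucose_units`` must declare mg/dL or
    mmol/L explicitly — no auto-detection.
    """
    if glucose_units not in ("mmol/L", "mg/dL"):
        raise ValueError("glucose_units must be 'mmol/L' or 'mg/dL'")
    factor = 1.0 if glucose_units == "mmol/L" else MMOL_PER_MGDL_GLUCOSE
    dm = pd.Series(False, index=df.index)
    if fg_col in df.columns:
        dm |= df[fg_col] * factor >= 7.0
    if ogtt_col and ogtt_col in df.columns:
        dm |= df[ogtt_col] * factor >= 11.1
    if hba1c_col and hba1c_col in df.columns:
        dm |= df[hba1c_col] >= 6.5
    if history_col and history_col in df.columns:
        dm |= df[history_col] == 1
    return dm.astype(int)


def derive_htn(
    df: pd.DataFrame,
    sbp_col: str = "sbp",
    dbp_col: str = "dbp",
    medication_col: str | None = "htn_med",
) -> pd.Series:
    """Hypertension from medication history or BP >= 140/90 mmHg."""
    htn = pd.Series(False, index=df.index)
    if sbp_col in df.columns:
        htn |= df[sbp_col] >= 140
    if dbp_col in df.columns:
        htn |= df[dbp_col] >= 90
    if medication_col and medication_col in df.columns:
        htn |= df[medication_col] == 1
    return htn.astype(int)


# ---------------------------------------------------------------------------
# result serialisation


def write_results(obj, path, format: str | None = None) -> Path:
    """Write a result artefact to CSV or JSON; round-trippable.

    Dispatches on type: contingency tables and cluster assignments go to
    CSV with a documented layout, k-selection traces to JSON, data frames
    / cohort tables to CSV, plain mappings to JSON.
    """
    from .rfc import ClusterAssignment, ContingencyTable, KSelectionResult

    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format not in ("csv", "json"):
        raise ValueError("format must be 'csv' or 'json'")

    if isinstance(obj, ContingencyTable):
        obj.to_frame().to_csv(path, index_label="group")
    elif isinstance(obj, ClusterAssignment):
        obj.to_frame().to_csv(path, index=False)
    elif isinstance(obj, KSelectionResult):
        path.write_text(obj.to_json())
    elif isinstance(obj, CohortTable):
        obj.df.to_csv(path, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    elif isinstance(obj, Mapping):
        path.write_text(json.dumps(obj, indent=2, default=float))
    else:
        raise TypeError(f"no serialisation rule for {type(obj).__name__}")
    return path


def load_contingency(path):
    from .rfc import ContingencyTable

    df = pd.read_csv(path, index_col="group")
    return ContingencyTable(ndm=df.loc["ndm"].to_numpy(), dm=df.loc["dm"].to_numpy())


def load_assignment(path):
    from .rfc import ClusterAssignment

    df = pd.read_csv(path)
    labels = df["cluster"].to_numpy(dtype=int)
    return ClusterAssignment(
        labels=labels, k=int(labels.max()), participant_id=df["participant_id"].to_numpy()
    )


def load_k_selection(path):
    from .rfc import KSelectionResult

    payload = json.loads(Path(path).read_text())
    trace = {
        int(k): (v["statistic"], v["df"], v["log_p"])
        for k, v in payload["trace"].items()
    }
    return KSelectionResult(
        selected_k=payload["selected_k"],
        trace=trace,
        stopping_reason=payload["stopping_reason"],
    )
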