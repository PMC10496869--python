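"""Delimited-text schemas for the study inputs and result documents.

All tables are UTF-8 CSV with a header row; ages are decimal years.

cohort.csv
    individual_id, sex (M/F), entry_age, exit_age, one column per risk
    factor (level labels), prior_cancer, prior_cvd (booleans).
events.csv
    individual_id, disease_id, onset_age, primary (boolean).  Onsets at or
    before entry are pre-study reports; duplicates of the same
    (individual, disease, age) are dropped with a warning.
diseases.csv
    disease_id, chapter (Roman-numeral ICD-10 chapter label), icd10_codes
    (semicolon-separated 3-/4-character codes).
models.json
    A list of fitted per-disease Weibull model documents.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .weibull import DiseaseModel

__all__ = [
    "read_cohort",
    "read_events",
    "read_disease_definitions",
    "read_models",
    "write_models",
]

ROMAN_CHAPTERS = {
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
    "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX", "XXI", "XXII",
}


class SchemaError(ValueError):
    """An input table violates its documented schema."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric {col!r} in rows {list(bad[:5] + 2)} "
                          "(1-based, counting the header)")
    return vals


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "entry_age", "exit_age"], path)
    df["entry_age"] = _numeric(df, "entry_age", path)
    df["exit_age"] = _numeric(df, "exit_age", path)
    bad = df.index[~(df["entry_age"] < df["exit_age"]) | ~(df["entry_age"] > 0)]
    if len(bad):
        raise SchemaError(
            f"{path}: rows {list(bad[:5] + 2)} (1-based, counting the header) violate "
            "0 < entry_age < exit_age")
    if df["individual_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate individual_id values")
    for col in ("prior_cancer", "prior_cvd"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def read_events(path) -> pd.DataFrame:
    """Read and validate an event table, deduplicating repeat rows."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "disease_id", "onset_age"], path)
    df["onset_age"] = _numeric(df, "onset_age", path)
    if "primary" not in df:
        df["primary"] = True
    df["primary"] = df["primary"].astype(bool)
    dup = df.duplicated(subset=["individual_id", "disease_id", "onset_age"])
    if dup.any():
        warnings.warn(f"{path}: dropped {int(dup.sum())} duplicate "
                      "(individual, disease, age) events")
        df = df[~dup]
    return df.reset_index(drop=True)


def read_disease_definitions(path) -> pd.DataFrame:
    """Read and validate the disease-definition table."""
    df = pd.read_csv(path)
    _require_columns(df, ["disease_id", "chapter"], path)
    if df["disease_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate disease_id values")
    unknown = set(df["chapter"].astype(str)) - ROMAN_CHAPTERS
    if unknown:
        raise SchemaError(f"{path}: unknown chapter labels {sorted(unknown)}; "
                          "expected Roman numerals I..XXII")
    if "icd10_codes" not in df:
        df["icd10_codes"] = ""
    return df


def write_models(models, path) -> None:
    """Serialize fitted per-disease models to a JSON document."""
    docs = [m.to_dict() for m in models]
    Path(path).write_text(json.dumps(docs, indent=2))


def read_models(path) -> list[DiseaseModel]:
    docs = json.loads(Path(path).read_text())
    return [DiseaseModel.from_dict(d) for d in docs]
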