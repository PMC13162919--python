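"""Cohort table and taxonomy CSV round-trip with validation."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .synthetic import CohortTable

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = [
    "id",
    "time_years",
    "event",
    "age",
    "gender",
    "overall_stage",
    "t_stage",
    "n_stage",
]

_STAGE_ALIASES = {"i": 1, "ii": 2, "iii": 3, "1": 1, "2": 2, "3": 3}


def write_cohort(cohort: CohortTable, out_dir, prefix: str = "cohort"):
    """Write the patient table and the two-column taxonomy CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_path = out_dir / f"{prefix}.csv"
    tax_path = out_dir / f"{prefix}_taxonomy.csv"
    cohort.data.to_csv(cohort_path, index=False)
    pd.DataFrame(
        {"feature": cohort.feature_names,
         "family": [cohort.taxonomy[f] for f in cohort.feature_names]}
    ).to_csv(tax_path, index=False)
    return cohort_path, tax_path


def read_cohort(cohort_path, taxonomy_path) -> CohortTable:
    """Load and validate a cohort CSV plus its feature taxonomy.

    Rows with missing values in any required or feature column are
    dropped with a logged count; stage labels are normalised to 1/2/3.
    """
    df = pd.read_csv(cohort_path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    tax = pd.read_csv(taxonomy_path)
    if not {"feature", "family"}.issubset(tax.columns):
        raise ValueError("taxonomy CSV must have 'feature' and 'family' columns")
    taxonomy = dict(zip(tax["feature"], tax["family"]))
    extra = {"tumor_count"}
    feature_names = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c not in extra
    ]
    missing_tax = [f for f in feature_names if f not in taxonomy]
    if missing_tax:
        raise ValueError(
            f"features absent from taxonomy: {missing_tax[:5]}"
            + ("..." if len(missing_tax) > 5 else "")
        )
    before = len(df)
    df = df.dropna(subset=REQUIRED_COLUMNS + feature_names).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d rows with incomplete records", dropped)

    def norm_stage(v):
        key = str(v).strip().lower().removeprefix("stage").strip()
        if key in _STAGE_ALIASES:
            return _STAGE_ALIASES[key]
        raise ValueError(f"unrecognised overall_stage value {v!r}")

    df["overall_stage"] = df["overall_stage"].map(norm_stage)
    df["gender"] = df["gender"].astype(str).str.strip().str.lower()
    if not set(df["gender"]).issubset({"male", "female"}):
        raise ValueError("gender must be coded male/female")
    df["event"] = df["event"].astype(int)
    table = CohortTable(
        data=df,
        taxonomy={f: taxonomy[f] for f in feature_names},
        feature_names=feature_names,
    )
    table.validate()
    return table
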