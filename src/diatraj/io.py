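"""Reading and writing cohort tables.

A cohort on disk is a directory with two UTF-8 CSV files, ``participants.csv``
and ``exams.csv``, header row included, with ``NA`` as the missing-value
token.  Column names match the in-memory DataFrames produced by
:func:`diatraj.simulate.simulate_cohort`; external data prepared in the same
layout is read identically.  Precomputed ``homa_b`` / ``homa_ir`` columns in
``exams.csv`` are optional and, when present, take precedence over internal
HOMA computation downstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ParseError

MISSING_TOKEN = "NA"

PARTICIPANT_COLUMNS = {
    "participant_id": str,
    "group": str,
    "sex": str,
    "fhd": str,
    "gada_positive": bool,
    "baseline_age": float,
    "diagnosis_time": float,
    "diagnosed_via_registry": bool,
    "classification_exam": int,
    "exams_attended": str,
}

EXAM_COLUMNS = {
    "participant_id": str,
    "exam_index": int,
    "exam_time": float,
    "age": float,
    "fpg": float,
    "glucose_2h": float,
    "fasting_insulin": float,
    "bmi": float,
    "whr": float,
    "sbp": float,
    "dbp": float,
    "smoking": str,
    "education": str,
    "physical_activity": str,
    "bp_medication": bool,
}

OPTIONAL_EXAM_COLUMNS = {"homa_b": float, "homa_ir": float}


def write_cohort(participants: pd.DataFrame, exams: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort to ``path`` as ``participants.csv`` + ``exams.csv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    participants.to_csv(path / "participants.csv", index=False, na_rep=MISSING_TOKEN)
    exams.to_csv(path / "exams.csv", index=False, na_rep=MISSING_TOKEN)
    return path


def _read_table(file: Path, schema: dict, optional: dict | None = None) -> pd.DataFrame:
    if not file.exists():
        raise ParseError(f"cohort file not found: {file}")
    try:
        df = pd.read_csv(
            file,
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
            dtype=str,
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"malformed CSV in {file.name}: {exc}") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ParseError(f"{file.name} is missing required column(s): {', '.join(missing)}")
    columns = {**schema, **(optional or {})}
    for col, typ in columns.items():
        if col not in df.columns:
            continue
        raw = df[col]
        try:
            if typ is float:
                df[col] = pd.to_numeric(raw, errors="raise").astype(float)
            elif typ is int:
                df[col] = pd.to_numeric(raw, errors="raise").astype(int)
            elif typ is bool:
                bad = ~raw.isin(["True", "False"]) & raw.notna()
                if bad.any():
                    raise ValueError(f"non-boolean value {raw[bad].iloc[0]!r}")
                df[col] = raw == "True"
            else:
                df[col] = raw.astype(object).where(raw.notna(), other=None)
                df[col] = df[col].fillna("")
        except (ValueError, TypeError) as exc:
            bad_idx = _first_bad_row(raw, typ)
            raise ParseError(
                f"{file.name}: cannot parse column {col!r}: {exc}",
                line=None if bad_idx is None else bad_idx + 2,  # +1 header, +1 one-based
            ) from exc
    return df


def _first_bad_row(raw: pd.Series, typ) -> int | None:
    for i, v in enumerate(raw):
        if pd.isna(v):
            continue
        try:
            if typ is bool:
                if v not in ("True", "False"):
                    return i
            else:
                typ(v)
        except (ValueError, TypeError):
            return i
    return None


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort directory; inverse of :func:`write_cohort`.

    Raises :class:`ParseError` naming the offending file/column (with a line
    number for value-level failures).  An empty exam table is valid.
    """
    path = Path(path)
    participants = _read_table(path / "participants.csv", PARTICIPANT_COLUMNS)
    exams = _read_table(path / "exams.csv", EXAM_COLUMNS, OPTIONAL_EXAM_COLUMNS)
    dup = participants["participant_id"].duplicated()
    if dup.any():
        raise ParseError(
            f"participants.csv: duplicate participant_id {participants['participant_id'][dup].iloc[0]!r}"
        )
    if len(exams):
        dup = exams.duplicated(subset=["participant_id", "exam_index"])
        if dup.any():
            pid = exams.loc[dup, "participant_id"].iloc[0]
            raise ParseError(f"exams.csv: duplicate (participant_id, exam_index) for {pid!r}")
    return participants, exams
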