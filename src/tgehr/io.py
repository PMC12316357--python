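"""Plain-text round-trip of event, patient and cohort tables.

Events and patients travel as CSV with ISO-8601 dates. The latent severity
trajectory (generator ground truth) is serialized as a ``|``-joined list of
repr-precision floats so read(write(x)) reproduces it exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["patient_id", "date", "code", "source"]
PATIENT_COLUMNS = [
    "patient_id",
    "age_at_start",
    "sex",
    "imd",
    "replacement_date",
    "latent_severity_trajectory",
]
VALID_SOURCES = {"clinical", "prescription"}


class ParseError(ValueError):
    """Malformed row in a delimited input file; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    if len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_COLUMNS:
        raise ParseError(path, 1, f"expected header {EVENT_COLUMNS}, got {list(df.columns)}")
    dates = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.source not in VALID_SOURCES:
            raise ParseError(path, i, f"unknown source value {row.source!r}")
        try:
            dates.append(pd.Timestamp(row.date))
        except ValueError as exc:
            raise ParseError(path, i, f"bad date {row.date!r}") from exc
    df["date"] = pd.to_datetime(dates) if dates else pd.to_datetime(pd.Series([], dtype=object))
    return df


def _severity_to_str(traj) -> str:
    arr = np.asarray(traj, dtype=float)
    return "|".join(repr(float(v)) for v in arr)


def _severity_from_str(s: str) -> np.ndarray:
    if s == "":
        return np.array([], dtype=float)
    return np.array([float(v) for v in s.split("|")], dtype=float)


def write_patients(patients: pd.DataFrame, path) -> None:
    out = patients.copy()
    if len(out):
        out["replacement_date"] = pd.to_datetime(out["replacement_date"]).dt.strftime(
            "%Y-%m-%d"
        )
        out["replacement_date"] = out["replacement_date"].fillna("")
        if "latent_severity_trajectory" in out.columns:
            out["latent_severity_trajectory"] = out["latent_severity_trajectory"].map(
                _severity_to_str
            )
        else:
            out["latent_severity_trajectory"] = ""
    out.to_csv(path, index=False, columns=PATIENT_COLUMNS)


def read_patients(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != PATIENT_COLUMNS:
        raise ParseError(path, 1, f"expected header {PATIENT_COLUMNS}, got {list(df.columns)}")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.sex not in {"female", "male"}:
            raise ParseError(path, i, f"unknown sex value {row.sex!r}")
        try:
            imd = int(row.imd)
            age = int(row.age_at_start)
        except ValueError as exc:
            raise ParseError(path, i, "age_at_start and imd must be integers") from exc
        if not 1 <= imd <= 5:
            raise ParseError(path, i, f"imd quintile out of range: {imd}")
        try:
            rep = pd.Timestamp(row.replacement_date) if row.replacement_date else pd.NaT
        except ValueError as exc:
            raise ParseError(path, i, f"bad date {row.replacement_date!r}") from exc
        rows.append(
            {
                "patient_id": row.patient_id,
                "age_at_start": age,
                "sex": row.sex,
                "imd": imd,
                "replacement_date": rep,
                "latent_severity_trajectory": _severity_from_str(
                    row.latent_severity_trajectory
                ),
            }
        )
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for col in ("index_date", "censor_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "matched_to": str})
    for col in ("index_date", "censor_date"):
        df[col] = pd.to_datetime(df[col])
    return df
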