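"""Strict CSV schemas for feeding-trial and survey tables.

Both formats are plain UTF-8 comma-delimited CSV with "." decimals.  Lines
starting with ``#`` before the header carry provenance metadata (seed,
config hash, package version) and are ignored on read.  Validation is
strict — malformed rows are reported with their row identifiers rather than
silently coerced.

Trial schema:  trial_id, predator_class, n_initial, n_consumed, duration_days
Survey schema: head_id, hawkfish (none|small|large), one 0/1 column per
species named ``<species>_present``, optional length_cm/width_cm/height_cm.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .cooccur import CATEGORIES, SurveyTable
from .fr_fit import TrialDataset

__all__ = ["SchemaError", "read_trials", "write_trials", "read_survey", "write_survey"]

TRIAL_COLUMNS = ["trial_id", "predator_class", "n_initial", "n_consumed", "duration_days"]
SURVEY_FIXED = ["head_id", "hawkfish"]
SURVEY_OPTIONAL = ["length_cm", "width_cm", "height_cm"]


class SchemaError(ValueError):
    """A table violated its schema; the message names the offending rows."""


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)


def _metadata_header(metadata: dict | None) -> str:
    from . import __version__

    lines = [f"# coralpred {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def _require_int(frame: pd.DataFrame, column: str, label_col: str) -> pd.Series:
    converted = pd.to_numeric(frame[column], errors="coerce")
    bad = converted.isna() | (converted != converted.round())
    if bad.any():
        rows = frame.loc[bad, label_col].tolist()
        raise SchemaError(f"column {column!r} must be integer; bad rows: {rows}")
    return converted.astype(int)


def read_trials(path) -> TrialDataset:
    """Read and validate a feeding-trial CSV into a :class:`TrialDataset`."""
    frame = _read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    if len(frame) == 0:
        return TrialDataset([])
    frame = frame[TRIAL_COLUMNS].copy()
    frame["n_initial"] = _require_int(frame, "n_initial", "trial_id")
    frame["n_consumed"] = _require_int(frame, "n_consumed", "trial_id")
    duration = pd.to_numeric(frame["duration_days"], errors="coerce")
    if duration.isna().any() or (duration <= 0).any():
        rows = frame.loc[duration.isna() | (duration <= 0), "trial_id"].tolist()
        raise SchemaError(f"duration_days must be > 0; bad rows: {rows}")
    frame["duration_days"] = duration
    over = frame["n_consumed"] > frame["n_initial"]
    if over.any():
        raise SchemaError(
            f"n_consumed exceeds n_initial in rows: {frame.loc[over, 'trial_id'].tolist()}"
        )
    if (frame["n_consumed"] < 0).any() or (frame["n_initial"] < 1).any():
        bad = (frame["n_consumed"] < 0) | (frame["n_initial"] < 1)
        raise SchemaError(f"invalid counts in rows: {frame.loc[bad, 'trial_id'].tolist()}")
    return TrialDataset.from_frame(frame)


def write_trials(data: TrialDataset, path, metadata: dict | None = None) -> None:
    """Write a trial dataset to CSV with a provenance comment header."""
    path = Path(path)
    buf = _io.StringIO()
    data.to_frame().to_csv(buf, index=False)
    path.write_text(_metadata_header(metadata) + buf.getvalue(), encoding="utf-8")


def read_survey(path) -> SurveyTable:
    """Read and validate a coral-head survey CSV into a :class:`SurveyTable`."""
    frame = _read_csv(path)
    missing = [c for c in SURVEY_FIXED if c not in frame.columns]
    if missing:
        raise SchemaError(f"survey table missing columns: {missing}")
    species_cols = [c for c in frame.columns if c.endswith("_present")]
    if not species_cols:
        raise SchemaError("survey table has no *_present species columns")
    bad_cat = ~frame["hawkfish"].isin(CATEGORIES)
    if bad_cat.any():
        rows = frame.loc[bad_cat, "head_id"].tolist()
        raise SchemaError(f"unknown hawkfish category in rows: {rows}")
    for col in species_cols:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = ~values.isin([0, 1])
        if bad.any():
            rows = frame.loc[bad, "head_id"].tolist()
            raise SchemaError(f"column {col!r} must be 0/1; bad rows: {rows}")
        frame[col] = values.astype(int)
    for col in SURVEY_OPTIONAL:
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    keep = SURVEY_FIXED + species_cols + [c for c in SURVEY_OPTIONAL if c in frame.columns]
    return SurveyTable(data=frame[keep].reset_index(drop=True))


def write_survey(table: SurveyTable, path, metadata: dict | None = None) -> None:
    """Write a survey table to CSV with a provenance comment header."""
    path = Path(path)
    buf = _io.StringIO()
    table.data.to_csv(buf, index=False)
    merged = dict(table.metadata or {})
    merged.update(metadata or {})
    path.write_text(_metadata_header(merged) + buf.getvalue(), encoding="utf-8")
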