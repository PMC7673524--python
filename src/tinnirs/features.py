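"""Feature-table reading and writing.

The canonical on-disk form is a wide CSV: one row per subject, metadata
columns (subject, group, thi, loudness, annoyance, duration_years, age,
hearing thresholds) followed by named feature columns.  An XLSX reader
accepts supplementary-data-style sheets (subject rows, feature columns)
with tolerant header normalisation and emits the canonical CSV.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .pipeline import METADATA_COLUMNS

_HEADER_ALIASES = {
    "id": "subject",
    "participant": "subject",
    "subject_id": "subject",
    "thi_score": "thi",
    "duration": "duration_years",
    "tinnitus_duration": "duration_years",
}


def normalise_header(name: str) -> str:
    """Collapse whitespace/punctuation to underscores and map metadata aliases.

    Metadata columns are matched case-insensitively against known aliases;
    feature column names keep their case (HbO/HbR tags are meaningful).
    """
    clean = re.sub(r"[^0-9a-zA-Z]+", "_", str(name).strip()).strip("_")
    lowered = clean.lower()
    if lowered in _HEADER_ALIASES:
        return _HEADER_ALIASES[lowered]
    if lowered in METADATA_COLUMNS:
        return lowered
    return clean


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    feat = sorted(c for c in table.columns if c not in METADATA_COLUMNS)
    return table[meta + feat]


def read_feature_xlsx(path, sheet=0) -> pd.DataFrame:
    """Read a subject-by-feature XLSX sheet into the canonical table.

    Headers are normalised; blank cells become NaN (the missing-value
    mask); column order is irrelevant because columns are name-keyed.
    """
    try:
        raw = pd.read_excel(path, sheet_name=sheet)
    except Exception as err:  # pragma: no cover - depends on file corruption mode
        raise ValueError(f"unparseable XLSX sheet: {err}") from err
    raw.columns = [normalise_header(c) for c in raw.columns]
    if raw.columns.duplicated().any():
        dupes = list(raw.columns[raw.columns.duplicated()])
        raise ValueError(f"duplicate feature columns after normalisation: {dupes}")
    for col in raw.columns:
        if col not in METADATA_COLUMNS and col != "subject":
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    meta = [c for c in METADATA_COLUMNS if c in raw.columns]
    feat = sorted(c for c in raw.columns if c not in METADATA_COLUMNS)
    return raw[meta + feat]


def missing_mask(table: pd.DataFrame) -> pd.DataFrame:
    feats = [c for c in table.columns if c not in METADATA_COLUMNS]
    return table[feats].isna()
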