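"""CSV/JSON reading and writing with validation and exact reproducibility.

Responses are exchanged as CSV with one row per respondent and one column
per item; empty cells are missing.  Machine-readable outputs are JSON with
sorted keys so identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping

import numpy as np
import pandas as pd

from .grm import ResponseMatrix

__all__ = ["read_responses", "write_responses", "read_cohort", "write_cohort",
           "write_json", "write_report", "file_sha256"]


class ResponseFormatError(ValueError):
    """Malformed response CSV; message carries row/column coordinates."""


def read_responses(path, n_categories: Mapping[str, int] | None = None) -> ResponseMatrix:
    """Read a response CSV (first column = respondent_id, empty = missing).

    Category codes must be integers; when ``n_categories`` declares K per
    item, codes are range-checked.  Errors cite the offending respondent
    and item.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.EmptyDataError, ValueError) as exc:
        raise ResponseFormatError(f"{path}: empty or unreadable response file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ResponseFormatError(f"{path}: no responses found")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ResponseFormatError(f"{path}: duplicate respondent_id {dup!r}")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = df.isna().to_numpy()
    bad = ~np.isfinite(arr) & ~raw_na
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ResponseFormatError(
            f"{path}: non-numeric cell at respondent {df.index[i]!r}, "
            f"item {df.columns[j]!r}"
        )
    obs = np.isfinite(arr)
    frac = arr[obs] - np.round(arr[obs])
    if np.any(np.abs(frac) > 1e-9):
        k = np.argwhere(obs)[np.flatnonzero(np.abs(frac) > 1e-9)[0]]
        raise ResponseFormatError(
            f"{path}: non-integer code at respondent {df.index[k[0]]!r}, "
            f"item {df.columns[k[1]]!r}"
        )
    if np.any(arr[obs] < 0):
        i, j = np.argwhere(obs & (np.where(obs, arr, 0) < 0))[0]
        raise ResponseFormatError(
            f"{path}: negative code at respondent {df.index[i]!r}, "
            f"item {df.columns[j]!r}"
        )
    if n_categories:
        for j, col in enumerate(df.columns):
            k = n_categories.get(str(col))
            if k is None:
                continue
            colobs = obs[:, j]
            over = colobs & (arr[:, j] > k - 1)
            if over.any():
                i = np.flatnonzero(over)[0]
                raise ResponseFormatError(
                    f"{path}: code {int(arr[i, j])} out of range 0..{k - 1} "
                    f"at respondent {df.index[i]!r}, item {col!r}"
                )
        ks = [n_categories.get(str(c)) for c in df.columns]
    else:
        ks = None
    mask = ~obs
    values = np.where(mask, 0, np.round(arr)).astype(np.int64)
    return ResponseMatrix(values, mask, df.columns, df.index, ks)


def write_responses(responses: ResponseMatrix, path) -> None:
    """Write responses as CSV; missing entries become empty cells."""
    df = responses.to_dataframe()
    out = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index_label="respondent_id")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index_label="respondent_id", float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="respondent_id")


def write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report(report, path) -> None:
    """Write an EvaluationReport (or plain mapping) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    write_json(payload, path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
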