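"""Delimited-text input and JSON output helpers shared by the CLI."""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd


def package_version() -> str:
    try:
        return version("elrt")
    except PackageNotFoundError:  # pragma: no cover - running from a source tree
        return "unknown"


def read_series(path, value_col: str | None = None, date_col: str | None = None, sep: str = ","):
    """Read a univariate series from delimited text.

    With no column names given, a single-column file is read as plain
    values; a two-column file is assumed to be (date, value).  Returns a
    pandas Series (date-indexed when dates are available).
    """
    frame = pd.read_csv(path, sep=sep)
    if value_col is None and date_col is None:
        if frame.shape[1] == 1:
            return pd.Series(pd.to_numeric(frame.iloc[:, 0], errors="raise").to_numpy(dtype=float))
        if frame.shape[1] == 2:
            date_col, value_col = frame.columns[0], frame.columns[1]
        else:
            raise ValueError(
                f"{path} has {frame.shape[1]} columns; pass explicit column names"
            )
    if value_col is None:
        raise ValueError("value column name required when date column is given")
    values = pd.to_numeric(frame[value_col], errors="raise").to_numpy(dtype=float)
    if date_col is not None:
        idx = pd.DatetimeIndex(pd.to_datetime(frame[date_col], errors="raise"))
        series = pd.Series(values, index=idx).sort_index()
    else:
        series = pd.Series(values)
    return series


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def json_record(payload: dict, seed=None, config=None) -> dict:
    """Wrap a result payload with provenance (version, seed, config hash)."""
    record = {"tool_version": package_version(), **payload}
    if seed is not None:
        record["seed"] = seed
    if config is not None:
        record["config_hash"] = config_hash(config)
    return record


def dump_json(record, path=None, indent: int = 2) -> str:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return str(obj)

    text = json.dumps(record, indent=indent, default=_default)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text
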