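"""CSV readers/writers and result rendering.

Two plain-text dialects are supported:

* long format, header ``group,value`` with group codes 1 and 2 — raw
  observations (counts, measurements, ordinal codes);
* frequency format, header ``category,group1,group2`` — an
  ordered-categorical table, categories in file order.

Both are comma-separated UTF-8 with '.' decimal.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .ranks import FrequencyTable

__all__ = [
    "read_long_csv",
    "read_frequency_csv",
    "write_long_csv",
    "write_frequency_csv",
    "report",
]


def read_long_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-group sample from a long-format CSV (`group,value`)."""
    df = pd.read_csv(path)
    if list(df.columns) != ["group", "value"]:
        raise ValueError(f"{path}: expected header 'group,value', "
                         f"got {','.join(map(str, df.columns))}")
    if df.empty:
        raise ValueError(f"{path}: empty file")
    groups = pd.to_numeric(df["group"], errors="coerce")
    values = pd.to_numeric(df["value"], errors="coerce")
    for col, series in (("group", groups), ("value", values)):
        bad = series.index[series.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
    bad = groups.index[~groups.isin([1, 2])]
    if len(bad):
        raise ValueError(f"{path}: group must be 1 or 2, offending line {bad[0] + 2}")
    x1 = values[groups == 1].to_numpy(dtype=float)
    x2 = values[groups == 2].to_numpy(dtype=float)
    if x1.size == 0 or x2.size == 0:
        missing = 1 if x1.size == 0 else 2
        raise ValueError(f"{path}: no observations for group {missing}")
    return x1, x2


def write_long_csv(path, sample1, sample2) -> None:
    x1 = np.asarray(sample1).ravel()
    x2 = np.asarray(sample2).ravel()
    df = pd.DataFrame({
        "group": np.concatenate([np.ones(x1.size, int), np.full(x2.size, 2)]),
        "value": np.concatenate([x1, x2]),
    })
    df.to_csv(path, index=False)


def read_frequency_csv(path) -> FrequencyTable:
    """Read an ordered-categorical table (`category,group1,group2`)."""
    df = pd.read_csv(path)
    if list(df.columns) != ["category", "group1", "group2"]:
        raise ValueError(f"{path}: expected header 'category,group1,group2', "
                         f"got {','.join(map(str, df.columns))}")
    if len(df) < 2:
        raise ValueError(f"{path}: need >= 2 categories")
    for col in ("group1", "group2"):
        w = pd.to_numeric(df[col], errors="coerce")
        bad = w.index[w.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
    return FrequencyTable(categories=tuple(df["category"].astype(str)),
                          weights1=df["group1"].to_numpy(dtype=float),
                          weights2=df["group2"].to_numpy(dtype=float))


def write_frequency_csv(path, table: FrequencyTable) -> None:
    pd.DataFrame({"category": list(table.categories),
                  "group1": table.weights1,
                  "group2": table.weights2}).to_csv(path, index=False)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def report(bundle: dict, fmt: str = "text") -> str:
    """Render a result bundle as an aligned text table or stable JSON.

    JSON keys are exactly the bundle keys (flattened dataclasses); the text
    form prints one `key: value` line per entry.
    """
    plain = _to_plain(bundle)
    if fmt == "json":
        return json.dumps(plain, indent=2, sort_keys=True)
    if fmt != "text":
        raise ValueError("format must be 'text' or 'json'")
    lines = []

    def emit(prefix, value):
        if isinstance(value, dict):
            for k, v in value.items():
                emit(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            if isinstance(value, float):
                value = f"{value:.6g}"
            lines.append(f"{prefix:<24} {value}")

    emit("", plain)
    return "\n".join(lines)
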