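"""Tabular output writing: curve CSVs and JSON property reports.

Curve files are plain CSV with a small ``# key: value`` comment header
carrying provenance (config hash, seed, scenario settings) so every
output is reproducible from the file alone plus the parameter file.
Floats are written at 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_curve_csv", "read_curve_csv", "write_report_json"]


def write_curve_csv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a curve table as CSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_curve_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a curve CSV written by :func:`write_curve_csv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def write_report_json(report: dict, path: str | Path) -> None:
    """Write a (property or calibration) report as indented JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, (set, tuple)):
        return list(obj)
    return str(obj)
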