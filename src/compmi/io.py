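"""Tabular I/O: trial and daily-matrix CSV in a single strict dialect.

Cells are ``0``, ``1`` or empty (missing); anything else is rejected with
the offending row and column.  Round trips are lossless, including missing
cells.  Configuration documents are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError

__all__ = [
    "read_binary_csv",
    "write_binary_csv",
    "read_trial_csv",
    "write_trial_csv",
    "validate_config",
]

TRIAL_COLUMNS = ("x", "z1", "z2", "z3")


def read_binary_csv(path, required: tuple[str, ...] = (), complete: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV of tri-state binary columns into nullable Int8.

    ``required`` columns must be present; ``complete`` columns must contain
    no missing cells.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] == 0 or len(raw) == 0:
        raise ConfigError(f"{path}: empty dataset (no rows)")
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ConfigError(f"{path}: missing required column(s) {missing_cols}")
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        values = raw[col].str.strip()
        bad = ~values.isin(["0", "1", ""])
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: malformed token {values[row]!r} in column {col!r}, "
                f"row {row + 2} (expected 0, 1 or empty)"
            )
        arr = pd.array(
            [pd.NA if v == "" else np.int8(v) for v in values], dtype="Int8"
        )
        out[col] = arr
    for col in complete:
        if col in out.columns and out[col].isna().any():
            raise ParseError(f"{path}: column {col!r} must not contain missing cells")
    return out


def write_binary_csv(data: pd.DataFrame, path) -> None:
    """Write tri-state columns with empty fields for missing cells."""
    data.to_csv(path, index=False, na_rep="")


def read_trial_csv(path) -> pd.DataFrame:
    """Read a trial dataset (x, z1, z2, z3[, y]); x and z1 must be complete."""
    return read_binary_csv(path, required=TRIAL_COLUMNS, complete=("x",))


def write_trial_csv(data: pd.DataFrame, path) -> None:
    write_binary_csv(data, path)


def validate_config(raw: dict, defaults: dict, exclusive: tuple[tuple[str, str], ...] = ()) -> dict:
    """Merge a JSON config block with defaults, rejecting unknown keys.

    Every violation is listed in a single error.  Re-validating a resolved
    config is a no-op (idempotent).
    """
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a JSON object, got {type(raw).__name__}")
    problems = []
    unknown = sorted(set(raw) - set(defaults))
    if unknown:
        problems.append(f"unknown key(s): {unknown}")
    for a, b in exclusive:
        if a in raw and b in raw and raw[a] is not None and raw[b] is not None:
            problems.append(f"keys {a!r} and {b!r} are mutually exclusive")
    resolved = {**defaults, **{k: v for k, v in raw.items() if k in defaults}}
    for key, default in defaults.items():
        if default is None or resolved[key] is None:
            continue
        if isinstance(default, bool) != isinstance(resolved[key], bool):
            problems.append(f"key {key!r}: expected {type(default).__name__}")
        elif isinstance(default, (int, float)) and not isinstance(resolved[key], (int, float)):
            problems.append(f"key {key!r}: expected a number, got {resolved[key]!r}")
        elif isinstance(default, str) and not isinstance(resolved[key], str):
            problems.append(f"key {key!r}: expected a string, got {resolved[key]!r}")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return resolved


def dump_resolved_config(config: dict, path) -> None:
    """Echo the fully resolved configuration next to a run's outputs."""
    Path(path).write_text(json.dumps(config, indent=2, default=str) + "\n")
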