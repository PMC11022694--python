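"""Tab-delimited readers and writers.

All tabular output is plain text with tab separators, mirroring the
device software's run log: one record per control tick with the columns

    time_s  pH  setpoint  color  intensity  kp  ki

The dialect is fixed: the header must match exactly (no column reordering)
and floats are written in shortest round-trip form, so
``read_log(write_log(records)) == records`` holds bit-for-bit and two runs
with the same seed produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .controller import LogRecord
from .errors import LogFormatError

__all__ = ["LOG_COLUMNS", "write_log", "read_log", "write_table", "read_table"]

LOG_COLUMNS = ("time_s", "pH", "setpoint", "color", "intensity", "kp", "ki")

_VALID_COLORS = {"red", "blue", "none"}


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(x))


def write_log(records: Iterable[LogRecord], path: str | Path) -> Path:
    """Write run-log records to ``path`` in the fixed tab dialect."""
    path = Path(path)
    lines = ["\t".join(LOG_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                (
                    _fmt(r.time_s),
                    _fmt(r.ph),
                    _fmt(r.setpoint),
                    r.color,
                    _fmt(r.intensity),
                    _fmt(r.kp),
                    _fmt(r.ki),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_log(path: str | Path) -> list[LogRecord]:
    """Read a run log, enforcing the exact column order and field types."""
    path = Path(path)
    lines = path.read_text().splitlines()
    expected_header = "\t".join(LOG_COLUMNS)
    if not lines or lines[0] != expected_header:
        raise LogFormatError(f"{path}: header must be exactly {expected_header!r}")
    records: list[LogRecord] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != len(LOG_COLUMNS):
            raise LogFormatError(
                f"{path}:{lineno}: expected {len(LOG_COLUMNS)} fields, got {len(parts)}"
            )
        try:
            color = parts[3]
            if color not in _VALID_COLORS:
                raise ValueError(f"invalid color {color!r}")
            records.append(
                LogRecord(
                    time_s=float(parts[0]),
                    ph=float(parts[1]),
                    setpoint=float(parts[2]),
                    color=color,
                    intensity=float(parts[4]),
                    kp=float(parts[5]),
                    ki=float(parts[6]),
                )
            )
        except ValueError as exc:
            raise LogFormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as a tab-delimited text table."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited table, optionally enforcing the column list."""
    df = pd.read_csv(path, sep="\t")
    if columns is not None and list(df.columns) != list(columns):
        raise LogFormatError(
            f"{path}: expected columns {list(columns)}, found {list(df.columns)}"
        )
    return df
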