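"""CSV input/output for growth datasets.

Schema: a header row followed by one row per measurement, either

    time_days,pd[,condition]
    time_days,fold_increase[,condition]

Comma-separated, dot decimal, UTF-8.  Values are written at 17 significant
digits so a write/read round trip reproduces every float bit-exactly.
Validation errors are row-addressed (1-based file rows, header = row 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datasets import GrowthDataset

__all__ = ["GrowthCsvError", "read_growth_csv", "write_growth_csv"]


class GrowthCsvError(ValueError):
    """Malformed growth CSV; ``row`` is the offending 1-based file row."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


def read_growth_csv(path: Union[str, Path]) -> GrowthDataset:
    """Parse a growth-curve CSV into a :class:`GrowthDataset`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise GrowthCsvError(f"{path}: file is empty") from None

    columns = [c.strip() for c in frame.columns]
    frame.columns = columns
    value_cols = [c for c in ("pd", "fold_increase") if c in columns]
    if "time_days" not in columns or len(value_cols) != 1:
        raise GrowthCsvError(
            f"{path}: header must be time_days plus exactly one of "
            f"pd / fold_increase (optional condition); got {columns}",
            row=1,
        )
    value_col = value_cols[0]
    extra = set(columns) - {"time_days", value_col, "condition"}
    if extra:
        raise GrowthCsvError(f"{path}: unknown column(s) {sorted(extra)}", row=1)

    times = _numeric_column(frame, "time_days", path)
    values = _numeric_column(frame, value_col, path)

    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]

    dup = np.nonzero(np.diff(times) == 0)[0]
    if dup.size:
        # report the file row of the second occurrence (pre-sort order)
        dup_time = times[dup[0] + 1]
        rows = np.nonzero(np.asarray(_numeric_column(frame, "time_days", path)) == dup_time)[0]
        raise GrowthCsvError(
            f"{path}: duplicate time {dup_time:g}", row=int(rows[-1]) + 2
        )

    if value_col == "fold_increase":
        bad = np.nonzero(values <= 0)[0]
        if bad.size:
            raise GrowthCsvError(
                f"{path}: fold_increase must be positive, got {values[bad[0]]:g}",
                row=int(order[bad[0]]) + 2,
            )

    condition = ""
    if "condition" in columns:
        labels = frame["condition"].fillna("").astype(str).str.strip().unique()
        labels = [lab for lab in labels if lab]
        if len(labels) > 1:
            raise GrowthCsvError(
                f"{path}: multiple condition labels in one file: {sorted(labels)}"
            )
        condition = labels[0] if labels else ""

    kwargs = {"pd_values": values} if value_col == "pd" else {"fold_values": values}
    try:
        return GrowthDataset(times=times, condition_label=condition, **kwargs)
    except ValueError as exc:
        raise GrowthCsvError(f"{path}: {exc}") from exc


def _numeric_column(frame: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    # parsed with Python's strtod-backed float() so that values written at
    # 17 significant digits round-trip bit-exactly
    raw = frame[column]
    values = np.empty(len(raw), dtype=float)
    for i, cell in enumerate(raw):
        try:
            values[i] = float(cell)
        except (TypeError, ValueError):
            raise GrowthCsvError(
                f"{path}: nonnumeric value {cell!r} in column {column}", row=i + 2
            ) from None
        if not np.isfinite(values[i]):
            raise GrowthCsvError(
                f"{path}: non-finite value {cell!r} in column {column}", row=i + 2
            )
    return values


def write_growth_csv(data: GrowthDataset, path: Union[str, Path]) -> None:
    """Write a dataset; ``read_growth_csv(write(...))`` is lossless."""
    path = Path(path)
    value_col = "pd" if data.representation == "pd" else "fold_increase"
    values = data.pd_values if data.representation == "pd" else data.fold_values
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"time_days,{value_col},condition\n")
        for t, v in zip(data.times, values):
            fh.write(f"{t:.17g},{v:.17g},{data.condition_label}\n")
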