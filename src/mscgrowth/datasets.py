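"""Growth-curve datasets: measured (time, cumulative PD) series.

A dataset stores either cumulative population doublings directly or
per-passage fold increases (the raw observable when cells are counted at
each subculture); the two are interconvertible via
``PD(t_k) = sum_{i<=k} log2 f(t_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import cumulative_pd_from_folds

__all__ = ["GrowthDataset"]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class GrowthDataset:
    """Measured growth curve for one culture condition.

    Exactly one of ``pd_values`` (cumulative population doublings) and
    ``fold_values`` (per-passage fold increases) is present; times are in
    days, strictly increasing, and nonnegative.
    """

    times: np.ndarray
    pd_values: Optional[np.ndarray] = None
    fold_values: Optional[np.ndarray] = None
    condition_label: str = ""

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        if times.size < 1:
            raise ValueError("a dataset needs at least one measurement")
        if times[0] < 0:
            raise ValueError("measurement times must be nonnegative")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("measurement times must be strictly increasing")
        object.__setattr__(self, "times", times)

        if (self.pd_values is None) == (self.fold_values is None):
            raise ValueError(
                "exactly one of pd_values / fold_values must be provided"
            )
        if self.pd_values is not None:
            pd = _as_float_array(self.pd_values, "pd_values")
            if pd.size != times.size:
                raise ValueError("times and pd_values must have equal length")
            object.__setattr__(self, "pd_values", pd)
        else:
            folds = _as_float_array(self.fold_values, "fold_values")
            if folds.size != times.size:
                raise ValueError("times and fold_values must have equal length")
            if np.any(folds <= 0):
                raise ValueError("fold increases must be positive")
            object.__setattr__(self, "fold_values", folds)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def pd(self) -> np.ndarray:
        """Cumulative PD series (accumulated from folds when needed)."""
        if self.pd_values is not None:
            return self.pd_values
        return cumulative_pd_from_folds(self.fold_values)

    @property
    def representation(self) -> str:
        return "pd" if self.pd_values is not None else "fold"
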