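"""Rank markers by average p-value and select the top N (or top percent).

Used before plotting/tabulation so that only the strongest markers are
displayed.  Ranking uses the arithmetic mean of the raw (untransformed)
p-values over the non-missing entries of each row; a marker whose row is
entirely missing sorts last.  Ties break by original input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ResultMatrix, ResultMatrixError

__all__ = ["SelectionSpec", "average_pvalue", "average_pvalues", "select_top"]


@dataclass(frozen=True)
class SelectionSpec:
    """Marker selection rule: top-``value`` by count, percent, or all.

    ``mode='count'`` requires a positive integer ``value``;
    ``mode='percent'`` requires ``0 < value <= 100`` (ceiling applied);
    ``mode='all'`` ignores ``value``.
    """

    mode: str = "all"
    value: float = 0

    def __post_init__(self) -> None:
        if self.mode not in {"count", "percent", "all"}:
            raise ValueError(f"invalid selection mode {self.mode!r}")
        if self.mode == "count":
            if self.value != int(self.value) or self.value < 1:
                raise ValueError("count mode requires a positive integer value")
        elif self.mode == "percent":
            if not 0 < self.value <= 100:
                raise ValueError("percent mode requires value in (0, 100]")

    def n_selected(self, n_markers: int) -> int:
        if self.mode == "all":
            return n_markers
        if self.mode == "count":
            return min(int(self.value), n_markers)
        return min(math.ceil(n_markers * self.value / 100.0), n_markers)


def average_pvalues(m: ResultMatrix) -> pd.Series:
    """Per-marker mean p-value over non-missing entries (NaN if none)."""
    with np.errstate(invalid="ignore"):
        return m.data.mean(axis=1, skipna=True)


def average_pvalue(m: ResultMatrix, marker: str) -> float:
    """Mean over non-missing entries of one marker's row.

    Returns NaN when every entry is missing; raises for unknown markers.
    """
    if marker not in m.data.index:
        raise ResultMatrixError(f"unknown marker id: {marker!r}")
    return float(m.data.loc[marker].mean(skipna=True))


def select_top(m: ResultMatrix, spec: SelectionSpec) -> ResultMatrix:
    """Sub-matrix of the markers with the smallest average p-values.

    Selects ``spec.n_selected(M)`` markers; within the result the
    original row order is preserved.  All-missing rows rank last and
    ties break by input order (stable sort).
    """
    n = spec.n_selected(m.n_markers)
    if n >= m.n_markers:
        return m
    avg = average_pvalues(m).to_numpy()
    # NaN (all-missing rows) must sort after every real average
    keys = np.where(np.isnan(avg), np.inf, avg)
    order = np.argsort(keys, kind="stable")[:n]
    keep_positions = np.sort(order)
    return ResultMatrix(m.data.iloc[keep_positions], source_path=m.source_path)
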