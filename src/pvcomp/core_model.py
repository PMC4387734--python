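"""P-value matrix data model and TSV interchange format.

The central object is :class:`ResultMatrix`: a dense markers x methods
table of p-values, one row per genetic marker (gene, probe, SNP, region)
and one column per analysis method.  Missing entries are represented as
``NaN`` internally and as ``NA`` on disk.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "P_FLOOR",
    "DEFAULT_MISSING_TOKENS",
    "ResultMatrix",
    "MissingPolicy",
    "ResultMatrixError",
    "read_result_table",
    "write_result_table",
    "filter_missing",
]

#: Floor applied to p-values before any log transform; -log10(0) is
#: undefined and real analysis tools do emit exact zeros.
P_FLOOR = 1e-300

#: Cell contents treated as missing when reading a table.
DEFAULT_MISSING_TOKENS = frozenset({"NA", "", "."})


class ResultMatrixError(ValueError):
    """Raised on malformed input tables or invalid matrix construction."""


class MissingPolicy(enum.Enum):
    """How markers with missing p-values are handled.

    ``DROP_ANY_MISSING`` removes every marker with at least one missing
    entry up front; ``PAIRWISE_COMPLETE`` keeps the matrix intact and
    lets each downstream operation use the pair-complete subset.
    """

    DROP_ANY_MISSING = "drop_any_missing"
    PAIRWISE_COMPLETE = "pairwise_complete"


@dataclass(frozen=True)
class ResultMatrix:
    """Dense markers x methods grid of p-values.

    Parameters
    ----------
    data :
        DataFrame indexed by marker id with one float column per method.
        ``NaN`` encodes a missing p-value.
    source_path :
        Optional provenance string (path the matrix was read from).

    Notes
    -----
    Construction validates uniqueness of marker ids and method names and
    that every finite entry lies in ``[0, 1]``.  Row order is canonical:
    it is the input file order and is used for tie-breaking everywhere.
    """

    data: pd.DataFrame
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ResultMatrixError("data must be a pandas DataFrame")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ResultMatrixError(f"duplicate marker id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ResultMatrixError(f"duplicate method name: {dup!r}")
        values = df.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ResultMatrixError(
                f"p-value out of [0, 1] at marker {df.index[i]!r}, "
                f"method {df.columns[j]!r}: {values[i, j]!r}"
            )
        if df.to_numpy(dtype=float, copy=False) is not values:
            object.__setattr__(self, "data", df.astype(float))

    # -- accessors -----------------------------------------------------

    @property
    def marker_ids(self) -> list[str]:
        return [str(m) for m in self.data.index]

    @property
    def method_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_markers(self) -> int:
        return self.data.shape[0]

    @property
    def n_methods(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pvalues(self) -> np.ndarray:
        """Dense float array of shape (n_markers, n_methods); NaN = missing."""
        return self.data.to_numpy(dtype=float)

    # -- construction helpers ------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        marker_ids: Sequence[str],
        method_names: Sequence[str],
        pvalues: np.ndarray | Sequence[Sequence[float]],
        source_path: str | None = None,
    ) -> "ResultMatrix":
        arr = np.asarray(pvalues, dtype=float)
        if arr.shape != (len(marker_ids), len(method_names)):
            raise ResultMatrixError(
                f"pvalues shape {arr.shape} does not match "
                f"({len(marker_ids)}, {len(method_names)})"
            )
        df = pd.DataFrame(arr, index=list(marker_ids), columns=list(method_names))
        return cls(df, source_path=source_path)

    def require_methods(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ResultMatrixError(f"unknown method name(s): {missing}")

    def column(self, method: str) -> pd.Series:
        self.require_methods([method])
        return self.data[method]

    def subset_methods(self, names: Sequence[str]) -> "ResultMatrix":
        self.require_methods(names)
        return ResultMatrix(self.data[list(names)], source_path=self.source_path)

    def subset_markers(self, ids: Sequence[str]) -> "ResultMatrix":
        unknown = [m for m in ids if m not in self.data.index]
        if unknown:
            raise ResultMatrixError(f"unknown marker id(s): {unknown[:5]}")
        return ResultMatrix(self.data.loc[list(ids)], source_path=self.source_path)

    def equals(self, other: "ResultMatrix") -> bool:
        if self.marker_ids != other.marker_ids:
            return False
        if self.method_names != other.method_names:
            return False
        a, b = self.pvalues, other.pvalues
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))


def read_result_table(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    min_methods: int = 2,
) -> ResultMatrix:
    """Read a tab-separated p-value table.

    The first row is a header: its first cell labels the marker column
    (any label is accepted) and the remaining cells name the methods.
    Each subsequent row is a marker id followed by one decimal p-value
    per method; tokens in ``missing_tokens`` become missing entries.

    Raises
    ------
    ResultMatrixError
        On duplicate marker ids, non-numeric cells, values outside
        ``[0, 1]``, rows of the wrong width, or fewer than 2 methods.
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    tokens = {str(t) for t in missing_tokens}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ResultMatrixError(f"{path}: empty file, expected a header row")
        method_names = [h.strip() for h in header[1:]]
        if len(method_names) < min_methods:
            raise ResultMatrixError(
                f"{path}: found {len(method_names)} method column(s); "
                f"at least {min_methods} are required"
            )
        if len(set(method_names)) != len(method_names):
            raise ResultMatrixError(f"{path}: duplicate method names in header")

        marker_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0].strip() == ""):
                continue  # tolerate blank trailing lines
            if len(row) != len(method_names) + 1:
                raise ResultMatrixError(
                    f"{path}:{lineno}: expected {len(method_names) + 1} "
                    f"fields, got {len(row)}"
                )
            marker = row[0].strip()
            if marker in seen:
                raise ResultMatrixError(f"{path}:{lineno}: duplicate marker id {marker!r}")
            seen.add(marker)
            parsed: list[float] = []
            for k, cell in enumerate(row[1:]):
                cell = cell.strip()
                if cell in tokens:
                    parsed.append(math.nan)
                    continue
                try:
                    value = float(cell)
                except ValueError:
                    raise ResultMatrixError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in "
                        f"column {method_names[k]!r}"
                    ) from None
                if math.isnan(value):
                    parsed.append(math.nan)
                    continue
                if not 0.0 <= value <= 1.0:
                    raise ResultMatrixError(
                        f"{path}:{lineno}: p-value {value!r} outside [0, 1] "
                        f"in column {method_names[k]!r}"
                    )
                parsed.append(value)
            marker_ids.append(marker)
            rows.append(parsed)

    arr = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(method_names)), dtype=float)
    )
    return ResultMatrix.from_arrays(marker_ids, method_names, arr, source_path=str(path))


def write_result_table(m: ResultMatrix, path: str | Path) -> Path:
    """Write ``m`` as the same TSV dialect :func:`read_result_table` reads.

    Missing entries are written as ``NA``; values use shortest
    round-trip decimal representation so read(write(m)) == m exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(["marker", *m.method_names]) + "\n")
        for marker, row in zip(m.marker_ids, m.pvalues):
            cells = [marker]
            for v in row:
                cells.append("NA" if math.isnan(v) else repr(float(v)))
            fh.write("\t".join(cells) + "\n")
    return path


def filter_missing(m: ResultMatrix, policy: MissingPolicy) -> ResultMatrix:
    """Apply a missing-value policy to a matrix.

    ``DROP_ANY_MISSING`` keeps exactly the markers whose rows have no
    missing entry (order preserved; an empty result is legal).
    ``PAIRWISE_COMPLETE`` returns the matrix unchanged.
    """
    if policy is MissingPolicy.PAIRWISE_COMPLETE:
        return m
    keep = ~np.isnan(m.pvalues).any(axis=1)
    return ResultMatrix(m.data.loc[keep], source_path=m.source_path)
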