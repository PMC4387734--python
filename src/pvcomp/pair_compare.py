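"""Pairwise comparison of method results.

Two views:

* an all-pairs correlation matrix of the methods' p-values (optionally
  on the -log10 scale), feeding the scatter-matrix report;
* a detailed two-method comparison: partition of markers into
  both/A-only/B-only/neither at chosen thresholds (the Venn view) and a
  sweep of those counts over a decreasing grid of cut-offs.

Significance is inclusive (``p <= alpha``).  Markers missing in either
member of a pair are excluded from that pair's statistics and reported
separately as "not comparable".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_model import P_FLOOR, ResultMatrix, ResultMatrixError

__all__ = [
    "CorrelationMatrix",
    "PairClassification",
    "SweepTable",
    "DEFAULT_SWEEP_CUTOFFS",
    "neglog10",
    "correlation_matrix",
    "classify_pair",
    "threshold_sweep",
]

#: Default cut-off grid for the threshold sweep.
DEFAULT_SWEEP_CUTOFFS = (0.05, 0.01, 0.005, 0.001)

_TRANSFORMS = ("neglog10", "raw")
_CORR_METHODS = ("pearson", "spearman")


def neglog10(p: np.ndarray | float, floor: float = P_FLOOR) -> np.ndarray | float:
    """-log10 of p with zeros clamped to ``floor`` (NaN passes through)."""
    return -np.log10(np.maximum(p, floor))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric K x K grid of between-method correlation coefficients.

    ``r[i, j]`` is the correlation of methods i and j over their
    pair-complete markers after applying ``transform``; NaN marks cells
    with fewer than 2 complete pairs (or zero variance).  ``n_used``
    holds the pair-complete marker counts.
    """

    method_names: list[str]
    r: np.ndarray
    transform: str
    method: str
    n_used: np.ndarray

    def value(self, a: str, b: str) -> float:
        i = self.method_names.index(a)
        j = self.method_names.index(b)
        return float(self.r[i, j])


@dataclass(frozen=True)
class PairClassification:
    """Venn partition of markers for two methods at given thresholds.

    The four lists are pairwise disjoint; their union is the set of
    pair-complete markers, in input order.  ``not_comparable`` holds
    markers missing in at least one of the two methods.
    """

    method_a: str
    method_b: str
    threshold_a: float
    threshold_b: float
    both: list[str]
    only_a: list[str]
    only_b: list[str]
    neither: list[str]
    not_comparable: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.both), len(self.only_a), len(self.only_b), len(self.neither))

    @property
    def n_compared(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class SweepRow:
    cutoff: float
    n_both: int
    n_only_a: int
    n_only_b: int
    n_neither: int


@dataclass(frozen=True)
class SweepTable:
    """Partition counts over a strictly decreasing grid of cut-offs.

    The same cut-off is applied to both methods in each row; for each
    row the four counts sum to the pair-complete marker count, and
    ``n_both`` is non-increasing as the cut-off decreases.
    """

    method_a: str
    method_b: str
    cutoffs: tuple[float, ...]
    rows: tuple[SweepRow, ...]


def _check_transform(transform: str, method: str) -> None:
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}, got {transform!r}")
    if method not in _CORR_METHODS:
        raise ValueError(f"method must be one of {_CORR_METHODS}, got {method!r}")


def correlation_matrix(
    m: ResultMatrix,
    transform: str = "neglog10",
    method: str = "pearson",
    floor: float = P_FLOOR,
) -> CorrelationMatrix:
    """All-pairs correlation of method results over pair-complete markers.

    Parameters
    ----------
    m :
        Input matrix with at least two methods.
    transform :
        ``'neglog10'`` (default) correlates ``-log10 p`` (zeros clamped
        to ``floor``); ``'raw'`` correlates the p-values directly.
    method :
        ``'pearson'`` or ``'spearman'``.

    Pairs with fewer than 2 complete markers, or with a constant column,
    yield NaN cells.  The diagonal is 1 wherever defined.
    """
    _check_transform(transform, method)
    if m.n_methods < 2:
        raise ResultMatrixError("correlation requires at least 2 methods")
    values = m.pvalues
    if transform == "neglog10":
        with np.errstate(divide="ignore"):
            values = neglog10(values, floor)
    K = m.n_methods
    r = np.full((K, K), np.nan)
    n_used = np.zeros((K, K), dtype=int)
    for i in range(K):
        for j in range(i, K):
            ok = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            n = int(ok.sum())
            n_used[i, j] = n_used[j, i] = n
            if n < 2:
                continue
            x, y = values[ok, i], values[ok, j]
            if i == j:
                r[i, i] = 1.0
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # zero variance: undefined
            if method == "pearson":
                coef = stats.pearsonr(x, y).statistic
            else:
                coef = stats.spearmanr(x, y).statistic
            r[i, j] = r[j, i] = float(coef)
    return CorrelationMatrix(
        method_names=m.method_names, r=r, transform=transform, method=method, n_used=n_used
    )


def _check_threshold(alpha: float, name: str) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"{name} must lie in (0, 1), got {alpha!r}")


def classify_pair(
    m: ResultMatrix,
    method_a: str,
    method_b: str,
    threshold_a: float,
    threshold_b: float | None = None,
) -> PairClassification:
    """Partition markers by joint significance under two methods.

    A marker is in ``both`` iff ``p_A <= threshold_a`` and
    ``p_B <= threshold_b`` (``threshold_b`` defaults to
    ``threshold_a``); ``only_a``/``only_b``/``neither`` follow.  List
    order is input marker order.
    """
    if threshold_b is None:
        threshold_b = threshold_a
    _check_threshold(threshold_a, "threshold_a")
    _check_threshold(threshold_b, "threshold_b")
    m.require_methods([method_a, method_b])

    pa = m.data[method_a].to_numpy(dtype=float)
    pb = m.data[method_b].to_numpy(dtype=float)
    markers = np.asarray(m.marker_ids, dtype=object)
    complete = ~np.isnan(pa) & ~np.isnan(pb)

    sig_a = complete & (pa <= threshold_a)
    sig_b = complete & (pb <= threshold_b)
    return PairClassification(
        method_a=method_a,
        method_b=method_b,
        threshold_a=threshold_a,
        threshold_b=threshold_b,
        both=list(markers[sig_a & sig_b]),
        only_a=list(markers[sig_a & ~sig_b]),
        only_b=list(markers[sig_b & ~sig_a]),
        neither=list(markers[complete & ~sig_a & ~sig_b]),
        not_comparable=list(markers[~complete]),
    )


def threshold_sweep(
    m: ResultMatrix,
    method_a: str,
    method_b: str,
    cutoffs: tuple[float, ...] | list[float] = DEFAULT_SWEEP_CUTOFFS,
) -> SweepTable:
    """Partition counts for a strictly decreasing list of cut-offs.

    Each row applies the same cut-off to both methods.  Raises if the
    grid is not strictly decreasing or leaves (0, 1).
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    for c in cutoffs:
        _check_threshold(c, "cutoff")
    if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError(f"cutoffs must be strictly decreasing, got {cutoffs}")
    rows = []
    for c in cutoffs:
        pc = classify_pair(m, method_a, method_b, c, c)
        rows.append(SweepRow(c, *pc.counts))
    return SweepTable(method_a=method_a, method_b=method_b, cutoffs=cutoffs, rows=tuple(rows))
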