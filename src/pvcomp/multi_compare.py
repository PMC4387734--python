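"""Simultaneous comparison of two or more methods.

Builds the color-coded significance table (rows = markers sorted by
ascending average p-value, columns = methods, each cell red when
significant at that method's threshold and green otherwise, with
intensity increasing in -log10 p), extracts commonly-significant
markers, and optionally attaches Fisher's combined p-value per marker.

Fisher's method treats the k combined p-values as independent:
``X^2 = -2 * sum(ln p_i)`` referred to a chi-square distribution with
``2k`` degrees of freedom.  When the p-values come from one dataset
analyzed by several methods that assumption is violated, so the
combined value is descriptive only; reports carry a standing caution
and :class:`CombinedResult` exposes an ``independence_warning`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import P_FLOOR, ResultMatrix, ResultMatrixError
from .rank_select import average_pvalues

__all__ = [
    "DEFAULT_SATURATION_P",
    "INDEPENDENCE_CAUTION",
    "ThresholdConfig",
    "ColorCode",
    "CombinedResult",
    "MultiTable",
    "fisher_combine",
    "color_for_cell",
    "build_multi_table",
    "common_significant",
]

#: p-value at (and below) which cell color intensity saturates at 1.
DEFAULT_SATURATION_P = 1e-10

#: Standing caution printed whenever combined p-values are reported for
#: one dataset analyzed by multiple methods.
INDEPENDENCE_CAUTION = (
    "Caution: Fisher's combined p-values assume independent inputs. "
    "When the combined p-values come from a single dataset analyzed by "
    "several methods, that assumption is violated and the combined "
    "value should be interpreted as a descriptive summary only."
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-method significance levels.

    Maps each method name to its own alpha in (0, 1); every method in a
    comparison must have exactly one entry.
    """

    alphas: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, a in self.alphas.items():
            if not 0.0 < float(a) < 1.0:
                raise ValueError(f"alpha for {name!r} must lie in (0, 1), got {a!r}")

    @classmethod
    def uniform(cls, methods: Sequence[str], alpha: float) -> "ThresholdConfig":
        return cls({name: float(alpha) for name in methods})

    def alpha_for(self, method: str) -> float:
        try:
            return float(self.alphas[method])
        except KeyError:
            raise ResultMatrixError(f"no significance threshold for method {method!r}") from None

    def covers(self, methods: Iterable[str]) -> None:
        missing = [name for name in methods if name not in self.alphas]
        if missing:
            raise ResultMatrixError(f"no significance threshold for method(s): {missing}")


@dataclass(frozen=True)
class ColorCode:
    """Cell color: hue ('red' = significant, 'green' = not) + intensity in [0, 1]."""

    hue: str
    intensity: float

    def css(self) -> str:
        """Inline CSS background color, white at intensity 0."""
        other = int(round(255 * (1.0 - self.intensity)))
        if self.hue == "red":
            return f"rgb(255,{other},{other})"
        return f"rgb({other},255,{other})"


@dataclass(frozen=True)
class CombinedResult:
    """Fisher's combined probability test result.

    ``statistic`` is ``-2 * sum(ln p_i)``; ``df = 2k`` where k is the
    number of p-values combined; ``combined_p`` is the upper tail of the
    chi-square distribution with ``df`` degrees of freedom.
    """

    statistic: float
    df: int
    combined_p: float
    independence_warning: bool = False


def fisher_combine(
    ps: Sequence[float] | np.ndarray,
    independence_warning: bool = False,
    floor: float = P_FLOOR,
) -> CombinedResult:
    """Combine p-values with Fisher's method.

    Missing (NaN) entries are dropped and the degrees of freedom
    adjusted; zeros are clamped to ``floor`` before taking logs.  At
    least one non-missing p-value is required.
    """
    arr = np.asarray(ps, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("fisher_combine requires at least one non-missing p-value")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    arr = np.maximum(arr, floor)
    x2 = float(-2.0 * np.sum(np.log(arr)))
    df = 2 * int(arr.size)
    if df == 2:
        # chi-square df-2 upper tail of -2 ln p is identically p; return it
        # directly so the k=1 identity is exact to the last bit
        combined = float(arr[0])
    else:
        combined = float(stats.chi2.sf(x2, df))
    return CombinedResult(
        statistic=x2, df=df, combined_p=combined, independence_warning=independence_warning
    )


def color_for_cell(
    p: float,
    alpha: float,
    saturation_p: float = DEFAULT_SATURATION_P,
    floor: float = P_FLOOR,
) -> ColorCode:
    """Map one cell's p-value to a red/green color code.

    Red iff ``p <= alpha``.  Red intensity scales logarithmically from 0
    at ``p = alpha`` to 1 at ``p <= saturation_p``; green intensity is 0
    for ``p >= 0.5`` and scales logarithmically up to the alpha
    boundary.  The exact scale is a rendering choice (the hue rule is
    the contract).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if not 0.0 < saturation_p < alpha:
        raise ValueError("saturation_p must lie in (0, alpha)")
    p_eff = max(p, floor)
    if p <= alpha:
        intensity = math.log10(alpha / p_eff) / math.log10(alpha / saturation_p)
        return ColorCode("red", min(1.0, intensity))
    if p >= 0.5 or alpha >= 0.5:
        return ColorCode("green", 0.0)
    intensity = math.log10(0.5 / p_eff) / math.log10(0.5 / alpha)
    return ColorCode("green", min(1.0, max(0.0, intensity)))


@dataclass(frozen=True)
class MultiTable:
    """Color-coded significance table for a subset of methods.

    Rows are ordered by ascending average p-value over the selected
    methods.  ``significant`` mirrors ``pvalues`` with the per-cell
    ``p <= alpha_method`` flag; ``colors`` holds a :class:`ColorCode`
    per cell; ``combined_p`` is present only when requested.
    """

    selected_methods: list[str]
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    colors: pd.DataFrame
    average_p: pd.Series
    thresholds: ThresholdConfig
    combined_p: pd.Series | None = None
    saturation_p: float = field(default=DEFAULT_SATURATION_P, compare=False)

    @property
    def marker_ids(self) -> list[str]:
        return [str(i) for i in self.pvalues.index]


def build_multi_table(
    m: ResultMatrix,
    methods: Sequence[str] | None = None,
    thresholds: ThresholdConfig | None = None,
    with_combined: bool = False,
    alpha: float = 0.05,
    saturation_p: float = DEFAULT_SATURATION_P,
) -> MultiTable:
    """Build the multi-method comparison table.

    Parameters
    ----------
    m :
        Input matrix.
    methods :
        Subset of method names to compare (default: all); at least 2.
    thresholds :
        Per-method alphas; defaults to a uniform ``alpha`` for every
        selected method.
    with_combined :
        Attach Fisher's combined p-value per marker (over the selected
        methods, missing entries dropped).
    """
    methods = list(methods) if methods is not None else m.method_names
    if len(methods) < 2:
        raise ResultMatrixError("multi-method comparison requires at least 2 methods")
    sub = m.subset_methods(methods)
    if thresholds is None:
        thresholds = ThresholdConfig.uniform(methods, alpha)
    thresholds.covers(methods)

    avg = average_pvalues(sub)
    keys = np.where(np.isnan(avg.to_numpy()), np.inf, avg.to_numpy())
    order = np.argsort(keys, kind="stable")
    pv = sub.data.iloc[order]
    avg = avg.iloc[order]

    sig = pd.DataFrame(index=pv.index, columns=pv.columns, dtype=bool)
    colors = pd.DataFrame(index=pv.index, columns=pv.columns, dtype=object)
    for name in methods:
        a = thresholds.alpha_for(name)
        col = pv[name].to_numpy(dtype=float)
        sig[name] = ~np.isnan(col) & (col <= a)
        colors[name] = [
            None if math.isnan(p) else color_for_cell(p, a, saturation_p) for p in col
        ]

    combined = None
    if with_combined:
        combined = pd.Series(
            [
                (
                    math.nan
                    if np.isnan(row).all()
                    else fisher_combine(row, independence_warning=True).combined_p
                )
                for row in pv.to_numpy(dtype=float)
            ],
            index=pv.index,
            name="combined_p",
        )

    return MultiTable(
        selected_methods=methods,
        pvalues=pv,
        significant=sig,
        colors=colors,
        average_p=avg,
        thresholds=thresholds,
        combined_p=combined,
        saturation_p=saturation_p,
    )


def common_significant(
    m: ResultMatrix,
    methods: Sequence[str] | None = None,
    thresholds: ThresholdConfig | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Markers significant under every selected method.

    Markers with a missing p-value in any selected method never
    qualify.  The result is ranked by ascending average p-value over
    the selected methods (ties by input order).
    """
    table = build_multi_table(m, methods=methods, thresholds=thresholds, alpha=alpha)
    mask = table.significant.all(axis=1)
    return [str(i) for i in table.pvalues.index[mask]]
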