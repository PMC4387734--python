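"""Synthetic p-value matrix generators.

Two simulators make every module testable without external data:

* :func:`simulate_pvalue_matrix` draws marker-wise vectors of latent
  z-scores from an equicorrelated Gaussian copula, shifts a fraction of
  markers ("signal") by a common effect, and converts each z-score to a
  one-sided upper-tail p-value.  Null columns are exactly Uniform(0,1);
  cross-method correlation is controlled by a single rho.
* :func:`simulate_two_group` builds a genes x samples normal expression
  matrix with a planted set of differentially expressed genes and runs
  three real two-group tests per gene (Welch t, Wilcoxon rank-sum with
  normal approximation, and a label-permutation test of the t
  statistic), yielding correlated multi-method p-values with the
  structure of a real differential-expression comparison.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_model import ResultMatrix

__all__ = [
    "SimulationSpec",
    "TwoGroupSpec",
    "TWO_GROUP_METHODS",
    "simulate_pvalue_matrix",
    "simulate_two_group",
    "two_group_de_ids",
]

#: Method column names produced by :func:`simulate_two_group`.
TWO_GROUP_METHODS = ("t_test", "wilcoxon", "permutation")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the copula p-value generator.

    ``rho`` is the equicorrelation of the latent z-scores across
    methods; ``pi1`` the fraction of signal markers; ``mu`` the mean
    shift added to all coordinates of a signal marker's z-vector
    (mu > 0 maps to small p-values under the one-sided conversion).
    """

    n_markers: int
    n_methods: int = 2
    rho: float = 0.0
    pi1: float = 0.0
    mu: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be positive")
        if self.n_methods < 2:
            raise ValueError("n_methods must be at least 2")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must lie in [0, 1]")
        if self.mu < 0.0:
            raise ValueError("mu must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TwoGroupSpec:
    """Parameters of the two-group expression simulator.

    ``fold_effect`` is the additive mean shift (in expression units)
    applied to group 2 for the planted DE genes; ``noise_sd`` the
    per-observation standard deviation.
    """

    n_genes: int
    n_per_group: int
    de_fraction: float = 0.0
    fold_effect: float = 1.0
    noise_sd: float = 1.0
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


def simulate_pvalue_matrix(spec: SimulationSpec) -> ResultMatrix:
    """Draw a markers x methods p-value matrix from the copula model.

    For each marker an equicorrelated K-vector of z-scores is drawn as
    ``z = sqrt(rho) * shared + sqrt(1 - rho) * independent``; signal
    markers (Bernoulli ``pi1``) get ``mu`` added to every coordinate;
    each z maps to ``p = P(Z > z)``.  Missing entries are sprinkled
    independently at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    M, K = spec.n_markers, spec.n_methods
    shared = rng.standard_normal(M)
    indep = rng.standard_normal((M, K))
    z = math.sqrt(spec.rho) * shared[:, None] + math.sqrt(1.0 - spec.rho) * indep
    is_signal = rng.random(M) < spec.pi1
    z[is_signal] += spec.mu
    p = stats.norm.sf(z)
    if spec.missing_rate > 0:
        p[rng.random((M, K)) < spec.missing_rate] = np.nan

    width = len(str(M))
    markers = [f"m{i + 1:0{width}d}" for i in range(M)]
    methods = [f"method_{k + 1}" for k in range(K)]
    return ResultMatrix.from_arrays(markers, methods, p)


def _welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch t statistic per row of two genes x samples blocks."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1) / n1
    v2 = y.var(axis=1, ddof=1) / n2
    denom = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / denom


def two_group_de_ids(spec: TwoGroupSpec) -> list[str]:
    """Identifiers of the planted DE genes (the first ``n_de`` rows)."""
    width = len(str(spec.n_genes))
    return [f"gene{i + 1:0{width}d}" for i in range(spec.n_de)]


def simulate_two_group(spec: TwoGroupSpec) -> ResultMatrix:
    """Simulate a two-group experiment and test each gene three ways.

    The expression matrix is ``N(0, noise_sd^2)`` with the first
    ``n_de`` genes shifted by ``fold_effect`` in group 2.  Per gene the
    returned columns are: Welch t-test, Wilcoxon rank-sum (normal
    approximation with tie correction), and a permutation test of the
    Welch t statistic over ``n_permutations`` label shuffles with the
    add-one estimate ``(b + 1) / (B + 1)``.

    The planted DE genes are always the first rows; recover their ids
    with :func:`two_group_de_ids`.
    """
    rng = np.random.default_rng(spec.seed)
    G, n = spec.n_genes, spec.n_per_group
    X = rng.normal(0.0, spec.noise_sd, size=(G, 2 * n))
    X[: spec.n_de, n:] += spec.fold_effect

    g1, g2 = X[:, :n], X[:, n:]
    t_res = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
    p_t = np.asarray(t_res.pvalue, dtype=float)

    mwu = stats.mannwhitneyu(g1, g2, axis=1, alternative="two-sided", method="asymptotic")
    p_w = np.asarray(mwu.pvalue, dtype=float)

    t_obs = np.abs(_welch_t(g1, g2))
    exceed = np.zeros(G, dtype=int)
    labels = np.arange(2 * n)
    for _ in range(spec.n_permutations):
        perm = rng.permutation(labels)
        xp = X[:, perm]
        t_perm = np.abs(_welch_t(xp[:, :n], xp[:, n:]))
        exceed += t_perm >= t_obs
    p_perm = (exceed + 1) / (spec.n_permutations + 1)

    width = len(str(G))
    markers = [f"gene{i + 1:0{width}d}" for i in range(G)]
    table = np.column_stack([p_t, p_w, p_perm])
    return ResultMatrix.from_arrays(markers, list(TWO_GROUP_METHODS), table)
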