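import numpy as np
import pytest

from pvcomp import ResultMatrix


@pytest.fixture
def tiny_matrix() -> ResultMatrix:
    """3 markers x 2 methods, no missing values."""
    return ResultMatrix.from_arrays(
        ["m1", "m2", "m3"],
        ["T", "W"],
        [[0.01, 0.04], [0.2, 0.01], [0.03, 0.5]],
    )


@pytest.fixture
def matrix_with_missing() -> ResultMatrix:
    return ResultMatrix.from_arrays(
        ["g1", "g2", "g3", "g4"],
        ["A", "B", "C"],
        [
            [0.1, 0.2, 0.3],
            [0.5, np.nan, 0.4],
            [0.9, 0.8, 0.7],
            [np.nan, np.nan, np.nan],
        ],
    )


def random_matrix(rng: np.random.Generator, n_markers: int, n_methods: int,
                  missing_rate: float = 0.0) -> ResultMatrix:
    """Plain uniform random matrix, independent of the package's simulator."""
    p = rng.random((n_markers, n_methods))
    if missing_rate > 0:
        p[rng.random((n_markers, n_methods)) < missing_rate] = np.nan
    return ResultMatrix.from_arrays(
        [f"m{i}" for i in range(n_markers)],
        [f"meth{k}" for k in range(n_methods)],
        p,
    )
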