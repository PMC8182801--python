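import numpy as np
import pytest

from thermex.cells import UnitCell


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)


def random_cell(rng, lo=4.0, hi=14.0, ang_lo=70.0, ang_hi=110.0):
    """A random valid (positive-definite) cell, not necessarily reduced."""
    while True:
        a, b, c = rng.uniform(lo, hi, size=3)
        try:
            return UnitCell(a, b, c, *rng.uniform(ang_lo, ang_hi, size=3))
        except ValueError:
            continue


@pytest.fixture(scope="session")
def unimodular_matrices():
    """All 3x3 integer matrices with entries in {-2..2} and det = +/-1."""
    vals = np.arange(-2, 3, dtype=np.int16)
    grid = np.stack(np.meshgrid(*[vals] * 9, indexing="ij"), axis=-1).reshape(-1, 3, 3)
    m = grid.astype(np.int64)
    det = (
        m[:, 0, 0] * (m[:, 1, 1] * m[:, 2, 2] - m[:, 1, 2] * m[:, 2, 1])
        - m[:, 0, 1] * (m[:, 1, 0] * m[:, 2, 2] - m[:, 1, 2] * m[:, 2, 0])
        + m[:, 0, 2] * (m[:, 1, 0] * m[:, 2, 1] - m[:, 1, 1] * m[:, 2, 0])
    )
    return m[np.abs(det) == 1].astype(float)
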