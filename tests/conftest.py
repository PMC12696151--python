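import numpy as np
import pytest

from kswave import Grid, ModelParams, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def quad_grid():
    return Grid.collocation(513)


@pytest.fixture(scope="session")
def params():
    return ModelParams(1.0, 1.0)


def dense_periodic_elliptic(mvals, x, P, Z):
    """Independent oracle: second-order FD solve of -Z phi'' + phi = P m with
    periodic value and (one-sided) derivative matching at +-1/2."""
    n = len(x)
    h = x[1] - x[0]
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(1, n - 1):
        A[i, i - 1] = -Z / h ** 2
        A[i, i] = 2 * Z / h ** 2 + 1
        A[i, i + 1] = -Z / h ** 2
        rhs[i] = P * mvals[i]
    A[0, 0] = 1.0
    A[0, n - 1] = -1.0
    A[n - 1, 0] = -3.0
    A[n - 1, 1] = 4.0
    A[n - 1, 2] = -1.0
    A[n - 1, n - 1] = -3.0
    A[n - 1, n - 2] = 4.0
    A[n - 1, n - 3] = -1.0
    return np.linalg.solve(A, rhs)
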