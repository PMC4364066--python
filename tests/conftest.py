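import numpy as np
import pytest

from kronpair import InteractionTable, SimilarityMatrix


@pytest.fixture
def small_table():
    """2x2 fully measured quantitative table."""
    return InteractionTable(
        ["d1", "d2"], ["t1", "t2"],
        np.array([[1.0, 2.0], [3.0, 4.0]]),
        np.ones((2, 2), dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140409)


def random_psd_similarity(rng, ids, rank=None):
    """Random symmetric PSD Gram matrix over the given ids."""
    n = len(ids)
    rank = rank or n
    B = rng.standard_normal((n, rank))
    return SimilarityMatrix(list(ids), B @ B.T)


def brute_force_ci(y, f):
    """O(n^2) double-loop concordance index, the independent oracle."""
    num, z = 0.0, 0
    n = len(y)
    for i in range(n):
        for j in range(n):
            if y[i] > y[j]:
                z += 1
                d = f[i] - f[j]
                num += 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
    return num / z if z else None


def kron_ridge_oracle(Y, Kd_vals, Kt_vals, lam):
    """Explicit (n_d n_t) x (n_d n_t) Kronecker kernel ridge solve.

    Uses the column-major identity vec(D A T^T) = kron(T, D) vec(A); returns
    the dual coefficient matrix A and in-sample predictions.
    """
    nd, nt = Y.shape
    K = np.kron(Kt_vals, Kd_vals)
    a = np.linalg.solve(K + lam * np.eye(nd * nt), Y.reshape(-1, order="F"))
    A = a.reshape(nd, nt, order="F")
    preds = (K @ a).reshape(nd, nt, order="F")
    return A, preds
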