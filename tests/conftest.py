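import numpy as np
import pytest

from l0em import RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_instance(seed, n=None, m=None, lam_scale=1.0):
    """Random dense regression instance for solver-equivalence checks."""
    r = np.random.default_rng(seed)
    n = int(r.integers(10, 51)) if n is None else n
    m = int(r.integers(5, 201)) if m is None else m
    X = r.standard_normal((n, m))
    y = r.standard_normal(n)
    return RegressionData(X, y)


def orthonormal_instance(z, seed=0):
    """Design with orthonormal columns and X'y equal to the given z."""
    z = np.asarray(z, dtype=float)
    m = z.size
    n = max(4 * m, 20)
    r = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(r.standard_normal((n, m)))
    return RegressionData(Q, Q @ z)


def brute_force_best_subset(data, lam):
    """Exhaustive best-subset minimum of the L0 objective (m <= ~12).

    Enumerates every support, least-squares refits, and returns
    (best objective, best support frozenset).
    """
    X, y = data.X, data.y
    m = X.shape[1]
    best_obj = 0.5 * float(y @ y)  # empty support
    best_sup = frozenset()
    for mask in range(1, 2**m):
        idx = [j for j in range(m) if mask >> j & 1]
        theta, *_ = np.linalg.lstsq(X[:, idx], y, rcond=None)
        resid = y - X[:, idx] @ theta
        obj = 0.5 * float(resid @ resid) + 0.5 * lam * len(idx)
        if obj < best_obj:
            best_obj, best_sup = obj, frozenset(idx)
    return best_obj, best_sup
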