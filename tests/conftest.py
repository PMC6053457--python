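import numpy as np
import pytest

import rsmga as r


@pytest.fixture(scope="session")
def table1():
    return r.load_fixture("table1")


@pytest.fixture(scope="session")
def table1_full():
    return r.table1_full_design()


@pytest.fixture(scope="session")
def table2():
    return r.load_fixture("table2")


@pytest.fixture(scope="session")
def published_model():
    return r.load_fixture("table3-model")


@pytest.fixture(scope="session")
def printed_stats():
    return r.load_fixture("table1-stats")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_concave_quadratic(seed: int, k: int = 4) -> "r.QuadraticModel":
    """A random negative-definite quadratic with stationary point near the
    unit box (sometimes outside it, exercising the boundary fallback)."""
    gen = np.random.default_rng(seed)
    m = gen.normal(size=(k, k))
    a = -(m @ m.T / k + 0.5 * np.eye(k))
    x0 = gen.uniform(-0.2, 1.2, k)
    g = -2 * a @ x0
    quad = np.diag(a)
    inter = {(i, j): 2 * a[i, j] for i in range(k) for j in range(i + 1, k)}
    return r.QuadraticModel.from_parts(
        [f"x{i + 1}" for i in range(k)], float(gen.normal()), g, quad, inter
    )


def grid_search_max(model, bounds, n: int = 50, chunk: int = 500_000) -> float:
    """Independent dense-grid oracle for the box maximum of a polynomial."""
    axes = [np.linspace(lo, hi, n) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    best = -np.inf
    for i in range(0, len(pts), chunk):
        best = max(best, float(np.max(model.predict(pts[i : i + chunk]))))
    return best
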