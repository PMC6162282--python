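import numpy as np
import pandas as pd
import pytest

from rppaflow import Edge, RppaMatrix, SignalingNetwork


@pytest.fixture
def small_matrix() -> RppaMatrix:
    """3 proteins x 4 time points, linear scale, baseline first."""
    values = pd.DataFrame(
        {
            "T1": [2.0, 1.0, 4.0],
            "T2": [4.0, 1.0, 2.0],
            "T3": [1.0, 1.0, 8.0],
            "T4": [2.0, 1.0, 4.0],
        },
        index=["AKT", "MTOR", "P53"],
    )
    return RppaMatrix(cell_line="X", values=values, baseline="T1", scale="linear")


@pytest.fixture
def chain_network() -> SignalingNetwork:
    """A -> B -> SINK with direct control edges."""
    return SignalingNetwork(
        edges=[Edge("A", "B", "direct"), Edge("B", "SINK", "direct")]
    )


def ols_oracle(x, y):
    """Closed-form simple OLS with intercept: slope, intercept, r, two-sided p.

    b = Sxy/Sxx, t = b / se(b), se(b)^2 = (SSE/(n-2)) / Sxx. Independent of
    scipy.stats.linregress.
    """
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    b = sxy / sxx
    a = y.mean() - b * x.mean()
    sse = syy - b * sxy
    r = sxy / np.sqrt(sxx * syy)
    if sse <= 0:
        return b, a, r, 0.0
    se_b = np.sqrt(sse / (n - 2) / sxx)
    tstat = b / se_b
    p = 2 * tdist.sf(abs(tstat), n - 2)
    return b, a, r, p


def bh_oracle(p):
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
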