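import numpy as np
import pytest

from tregsig import ExpressionMatrix, SimConfig, simulate_tils


@pytest.fixture
def five_cell_matrix() -> ExpressionMatrix:
    """Five cells with (CD4, LAIR2) = (5,5),(5,3),(3,5),(3,3),(6,7)."""
    values = np.array(
        [
            [5.0, 5.0, 3.0, 3.0, 6.0],  # CD4
            [5.0, 3.0, 5.0, 3.0, 7.0],  # LAIR2
        ]
    )
    return ExpressionMatrix(
        ["CD4", "LAIR2"], [f"c{i}" for i in range(1, 6)], values
    )


@pytest.fixture
def score_fixture_matrix() -> ExpressionMatrix:
    """Two genes over three samples: g1=(1,2,3), g2=(4,4,10)."""
    return ExpressionMatrix(
        ["g1", "g2"],
        ["s1", "s2", "s3"],
        np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 10.0]]),
    )


@pytest.fixture(scope="session")
def default_tils():
    """One default-config simulated TIL dataset, shared across tests."""
    config = SimConfig(seed=11)
    return simulate_tils(config)


# ---------------------------------------------------------------------------
# Independent oracles (never call the implementation they check)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Definitional step-up FDR: q_i = min over p_(j) >= p_i of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        mask = p >= p[i]
        q[i] = min(1.0, np.min(p[mask] * m / ranks[mask]))
    return q


def breslow_partial_loglik(beta: float, times, events, x) -> float:
    """The written-out single-covariate Breslow log partial likelihood."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in range(times.size):
        if events[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)


def grid_search_cox_beta(times, events, x, lo=-4.0, hi=4.0, step=1e-4) -> float:
    """Grid-search maximizer of the written-out Breslow partial likelihood."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    betas = np.arange(lo, hi + step / 2, step)
    ll = np.zeros_like(betas)
    for i in range(times.size):
        if events[i] == 1:
            risk = x[times >= times[i]]
            ll += betas * x[i] - np.log(np.exp(np.outer(betas, risk)).sum(axis=1))
    return float(betas[np.argmax(ll)])
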