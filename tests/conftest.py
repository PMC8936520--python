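import numpy as np
import pandas as pd
import pytest

from mir200.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Scaled-down study conditions for fast end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_patients=(40, 50),
        n_genes=200,
        n_true_targets=10,
        dwi_shape=(16, 16),
        image_shape=(128, 128),
        n_nuclei=12,
        n_tumors_per_group=4,
    )


@pytest.fixture
def tiny_matrix():
    """5 miRNAs x 4 samples with simple integer values."""
    return pd.DataFrame(
        np.arange(20, dtype=float).reshape(5, 4),
        index=[
            "hsa-miR-200a-5p",
            "hsa-miR-200a-3p",
            "hsa-miR-200b-5p",
            "hsa-miR-200b-3p",
            "hsa-miR-429",
        ],
        columns=[f"P{i}" for i in range(4)],
    )


# ---------------------------------------------------------------------------
# independent oracles used by several test modules
# ---------------------------------------------------------------------------

def efron_log_partial_likelihood(beta, time, event, x):
    """Direct implementation of the Efron-tie Cox partial log-likelihood."""
    beta = float(beta)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for tau in np.unique(time[event == 1]):
        deaths = (time == tau) & (event == 1)
        at_risk = time >= tau
        d = int(deaths.sum())
        eta_d = beta * x[deaths]
        sum_risk = np.exp(beta * x[at_risk]).sum()
        sum_dead = np.exp(eta_d).sum()
        ll += eta_d.sum()
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_dead)
    return ll


def logrank_oracle(time, event, group):
    """Two-group log-rank chi-square from the hypergeometric moment sums."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(time[event == 1]):
        at_risk = time >= tau
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        deaths = (time == tau) & (event == 1)
        d = int(deaths.sum())
        d1 = int((deaths & (group == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def km_oracle(time, event):
    """Hand product-limit computation; returns (times, survival)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ts = np.unique(time[event == 1])
    s = 1.0
    out = []
    for tau in ts:
        n = int((time >= tau).sum())
        d = int(((time == tau) & (event == 1)).sum())
        s *= 1.0 - d / n
        out.append((tau, s))
    return out


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


def holm_sidak_oracle(p):
    """Literal step-down Sidak definition with monotonicity enforcement."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj
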