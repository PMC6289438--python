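"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the smoother oracle
conditions the dense joint Gaussian directly, and the rank-test oracle
enumerates group assignments.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


def dense_smoother_oracle(
    months,
    obs_month,
    z,
    sigma0_sq,
    sigma1_sq,
    beta=0.0,
    x=None,
    m1_prior=(0.0, 100.0),
):
    """Smoothed marginals of a random-walk level by conditioning the dense
    joint Gaussian of (m_1..m_T, z_1..z_N)."""
    months = np.asarray(months)
    T = len(months)
    z = np.asarray(z, dtype=float)
    N = z.size
    idx = np.searchsorted(months, np.asarray(obs_month))
    # Cov(m_i, m_j) = P0 + sigma1^2 * min(i, j)  (0-based index)
    grid = np.minimum.outer(np.arange(T), np.arange(T))
    K = m1_prior[1] + sigma1_sq * grid
    mu_m = np.full(T, m1_prior[0])
    H = np.zeros((N, T))
    H[np.arange(N), idx] = 1.0
    offset = beta * np.asarray(x, dtype=float) if x is not None else 0.0
    mu_z = mu_m[idx] + offset
    S = H @ K @ H.T + sigma0_sq * np.eye(N)
    W = K @ H.T @ np.linalg.inv(S)
    mean = mu_m + W @ (z - mu_z)
    cov = K - W @ H @ K
    return mean, np.diag(cov).copy()


def mann_whitney_enumeration(group_a, group_b):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments,
    with midranks so ties are handled."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    mu = n_a * n_b / 2.0

    def u_of(subset):
        return ranks[list(subset)].sum() - n_a * (n_a + 1) / 2.0

    u_obs = u_of(range(n_a))
    dev = abs(u_obs - mu) - 1e-9
    hits = sum(
        1
        for subset in combinations(range(n_a + n_b), n_a)
        if abs(u_of(subset) - mu) >= dev
    )
    return u_obs, hits / comb(n_a + n_b, n_a)
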