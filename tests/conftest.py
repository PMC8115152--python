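"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the library's own code paths: connectivity
indices are recomputed with networkx path enumeration, OLS with raw normal
equations, Kennard-Stone with a naive O(n^3) re-scan, and the SVR dual with
a general-purpose SLSQP solve of the 2n-variable quadratic program.
"""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------- molecules

@pytest.fixture(scope="session")
def fixture_set():
    from skinperm import fixture_molecules

    return {f.name: f for f in fixture_molecules()}


# ------------------------------------------------------- connectivity oracle

def chi_oracle(mol, k: int, valence: bool) -> float:
    """Chi path index by exhaustive simple-path enumeration with networkx."""
    import networkx as nx

    from skinperm import heavy_graph

    g = heavy_graph(mol)
    deg = g.delta_v if valence else g.delta
    G = nx.Graph()
    G.add_nodes_from(range(g.n_vertices))
    G.add_edges_from(g.edges)
    if k == 0:
        return sum(deg[v] ** -0.5 for v in G.nodes if deg[v] > 0)
    total = 0.0
    for s in G.nodes:
        for t in G.nodes:
            if s >= t:
                continue
            for path in nx.all_simple_paths(G, s, t, cutoff=k):
                if len(path) == k + 1:
                    prod = 1.0
                    for v in path:
                        prod *= deg[v]
                    if prod > 0:
                        total += prod ** -0.5
    return total


# --------------------------------------------------------------- OLS oracle

def ols_normal_equations(X, y):
    """Coefficients (intercept first) from the raw normal equations."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.hstack([np.ones((len(X), 1)), X])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, dtype=float))


# ----------------------------------------------------- Kennard-Stone oracle

def kennard_stone_bruteforce(X, n_train):
    """Naive max-min selection recomputing every distance at every step."""
    X = np.asarray(X, dtype=float)
    n = len(X)

    def dist(i, j):
        return float(np.sqrt(((X[i] - X[j]) ** 2).sum()))

    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(i, j)
            if d > best[0]:
                best = (d, (i, j))
    order = list(best[1])
    while len(order) < n_train:
        cand_best = (-1.0, None)
        for c in range(n):
            if c in order:
                continue
            dmin = min(dist(c, s) for s in order)
            if dmin > cand_best[0]:
                cand_best = (dmin, c)
        order.append(cand_best[1])
    return order


# ------------------------------------------------------------ SVR QP oracle

def svr_qp_oracle(X, y, C, gamma, epsilon):
    """Solve the epsilon-SVR dual as a generic constrained QP (SLSQP).

    Returns ``(beta, b, dual objective in maximization form)``.
    """
    from scipy.optimize import minimize

    from skinperm.svr import kernel_matrix

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - mean) / scale
    K = kernel_matrix(Xs, Xs, gamma)
    n = len(y)

    def objective(z):
        a, astar = z[:n], z[n:]
        beta = a - astar
        return 0.5 * beta @ K @ beta + epsilon * z.sum() - y @ beta

    def grad(z):
        a, astar = z[:n], z[n:]
        kb = K @ (a - astar)
        return np.concatenate([kb + epsilon - y, -kb + epsilon + y])

    cons = [{"type": "eq",
             "fun": lambda z: z[:n].sum() - z[n:].sum(),
             "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}]
    res = minimize(objective, np.zeros(2 * n), jac=grad, method="SLSQP",
                   bounds=[(0.0, C)] * 2 * n, constraints=cons,
                   options={"maxiter": 2000, "ftol": 1e-14})
    z = res.x
    beta = z[:n] - z[n:]
    # bias from free support vectors of the oracle solution
    r = y - K @ beta
    G = np.concatenate([r - epsilon, r + epsilon])
    free = (z > 1e-6 * C) & (z < C * (1 - 1e-6))
    if free.any():
        b = float(np.mean(G[free]))
    else:
        up = np.concatenate([z[:n] < C - 1e-9, z[n:] > 1e-9])
        low = np.concatenate([z[:n] > 1e-9, z[n:] < C - 1e-9])
        b = float((np.max(np.where(up, G, -np.inf))
                   + np.min(np.where(low, G, np.inf))) / 2)
    W = -0.5 * beta @ K @ beta + y @ beta - epsilon * np.abs(beta).sum()
    return beta, b, float(W), (Xs, K, mean, scale)


# ------------------------------------------------- Golbraikh-Tropsha oracle

def gt_oracle(y, yp, ytrain_mean):
    """Transcription-independent recomputation of the validation battery."""
    y = np.asarray(y, float)
    yp = np.asarray(yp, float)
    out = {}
    out["q2_ext"] = 1 - ((y - yp) ** 2).sum() / ((y - ytrain_mean) ** 2).sum()
    k = (y * yp).sum() / (yp * yp).sum()
    kp = (y * yp).sum() / (y * y).sum()
    out["k"], out["k_prime"] = k, kp
    out["r0_sq"] = 1 - ((yp - k * yp) ** 2).sum() / ((yp - yp.mean()) ** 2).sum()
    out["r0_prime_sq"] = 1 - ((y - kp * y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    r = np.corrcoef(y, yp)[0, 1]
    out["r2"] = r * r
    out["rel_diff"] = abs(out["r2"] - out["r0_sq"]) / out["r2"]
    out["rel_diff_prime"] = abs(out["r2"] - out["r0_prime_sq"]) / out["r2"]
    return out
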