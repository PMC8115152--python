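"""Epsilon-insensitive support vector regression with an RBF kernel, solved
by an SMO-style maximal-violating-pair ascent on the dual, plus a real-coded
genetic algorithm for tuning (C, gamma) by m-fold cross-validation.

The dual problem, in the 2n variables (a_i, a_i*) with 0 <= a_i, a_i* <= C
and sum_i (a_i - a_i*) = 0, minimizes

    1/2 (a - a*)' K (a - a*) + eps * sum_i (a_i + a_i*) - sum_i y_i (a_i - a_i*)

and the regression function is f(x) = sum_i (a_i - a_i*) K(x_i, x) + b.
Inputs are standardized to zero mean / unit variance inside training and the
standardization is stored with the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SvrModel",
    "GaConfig",
    "rbf_kernel",
    "kernel_matrix",
    "train_svr",
    "predict_svr",
    "dual_objective",
    "ga_optimize",
]


def rbf_kernel(x_i, x_j, gamma: float) -> float:
    """Gaussian radial basis function exp(-gamma * ||x_i - x_j||^2)."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("vectors must have equal length")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(np.exp(-gamma * np.sum((x_i - x_j) ** 2)))


def kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """RBF Gram matrix between the rows of A and of B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-gamma * d2)


@dataclass
class SvrModel:
    """A trained epsilon-SVR model.

    ``beta`` holds the support coefficients a_i - a_i* per training point on
    the standardized inputs stored in ``X_scaled``; ``mean``/``scale`` are
    the training standardization.
    """

    beta: np.ndarray
    b: float
    C: float
    gamma: float
    epsilon: float
    X_scaled: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    y: np.ndarray = field(repr=False)
    n_iter: int = 0
    kkt_gap: float = 0.0

    @property
    def support_mask(self) -> np.ndarray:
        return np.abs(self.beta) > 1e-8

    @property
    def n_support(self) -> int:
        return int(self.support_mask.sum())

    def predict(self, X_new) -> np.ndarray:
        return predict_svr(self, X_new)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "skinperm-svr/1",
                "hyperparameters": {"C": self.C, "gamma": self.gamma,
                                    "epsilon": self.epsilon},
                "bias": self.b,
                "standardization": {"mean": self.mean.tolist(),
                                    "scale": self.scale.tolist()},
                "support_coefficients": self.beta.tolist(),
                "training_inputs_scaled": self.X_scaled.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SvrModel":
        d = json.loads(text)
        hp = d["hyperparameters"]
        beta = np.asarray(d["support_coefficients"], dtype=float)
        return cls(
            beta=beta,
            b=float(d["bias"]),
            C=float(hp["C"]),
            gamma=float(hp["gamma"]),
            epsilon=float(hp["epsilon"]),
            X_scaled=np.asarray(d["training_inputs_scaled"], dtype=float),
            mean=np.asarray(d["standardization"]["mean"], dtype=float),
            scale=np.asarray(d["standardization"]["scale"], dtype=float),
            y=np.zeros(len(beta)),
        )


def _smo(K: np.ndarray, y: np.ndarray, C: float, eps: float,
         tol: float, max_iter: int) -> tuple:
    """Maximal-violating-pair SMO on the 2n-variable dual.

    Index u < n is a_u (sign +1), u >= n is a_{u-n}* (sign -1).  Returns
    ``(beta, b, iterations, final KKT gap)``.
    """
    n = len(y)
    alpha = np.zeros(2 * n)
    sign = np.concatenate([np.ones(n), -np.ones(n)])
    base = np.concatenate([np.arange(n), np.arange(n)])
    f = np.zeros(n)  # K @ beta
    it = 0
    gap = np.inf
    while it < max_iter:
        r = y - f
        # G_u = -sign_u * grad_u : candidate value of b per point
        G = np.concatenate([r - eps, r + eps])
        up = np.concatenate([alpha[:n] < C - 1e-12, alpha[n:] > 1e-12])
        low = np.concatenate([alpha[:n] > 1e-12, alpha[n:] < C - 1e-12])
        Gu = np.where(up, G, -np.inf)
        Gl = np.where(low, G, np.inf)
        u = int(np.argmax(Gu))
        v = int(np.argmin(Gl))
        gap = Gu[u] - Gl[v]
        if gap < tol:
            break
        i, j = base[u], base[v]
        h = K[i, i] + K[j, j] - 2.0 * K[i, j]
        g = gap  # -(directional derivative) along (d_u, d_v) = (sign_u, -sign_v)
        t = g / h if h > 1e-12 else np.inf
        # box caps: alpha_u + sign_u * t in [0, C]; alpha_v - sign_v * t in [0, C]
        cap_u = (C - alpha[u]) if sign[u] > 0 else alpha[u]
        cap_v = alpha[v] if sign[v] > 0 else (C - alpha[v])
        t = min(t, cap_u, cap_v)
        if t <= 0:
            break
        alpha[u] += sign[u] * t
        alpha[v] -= sign[v] * t
        # beta changes by +t at i and -t at j
        if i == j:
            it += 1
            continue
        f += t * (K[:, i] - K[:, j])
        it += 1
    beta = alpha[:n] - alpha[n:]
    # bias from free support vectors; fall back to the midpoint of [M, m]
    r = y - f
    G = np.concatenate([r - eps, r + eps])
    free = ((alpha > 1e-8) & (alpha < C - 1e-8))
    if free.any():
        b = float(np.mean(G[free]))
    else:
        up = np.concatenate([alpha[:n] < C - 1e-12, alpha[n:] > 1e-12])
        low = np.concatenate([alpha[:n] > 1e-12, alpha[n:] < C - 1e-12])
        m = np.max(np.where(up, G, -np.inf))
        M = np.min(np.where(low, G, np.inf))
        b = float((m + M) / 2.0)
    return beta, b, it, float(max(gap, 0.0))


def train_svr(
    X,
    y,
    C: float,
    gamma: float,
    epsilon: float,
    tol: float = 1e-3,
    max_iter: Optional[int] = None,
) -> SvrModel:
    """Train epsilon-SVR on (X, y) with an RBF kernel.

    ``tol`` is the KKT stopping gap on the dual; ``max_iter`` defaults to
    a generous multiple of the sample count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training data")
    if len(y) < 2:
        raise ValueError("need at least two training points")
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    Xs = (X - mean) / scale
    K = kernel_matrix(Xs, Xs, gamma)
    if max_iter is None:
        max_iter = max(200_000, 2_000 * len(y))
    beta, b, it, gap = _smo(K, y, C, epsilon, tol, max_iter)
    return SvrModel(beta=beta, b=b, C=C, gamma=gamma, epsilon=epsilon,
                    X_scaled=Xs, mean=mean, scale=scale, y=y,
                    n_iter=it, kkt_gap=gap)


def predict_svr(model: SvrModel, X_new) -> np.ndarray:
    """Kernel expansion sum_i beta_i K(x_i, x) + b on the training scaling."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_scaled.shape[1]:
        raise ValueError(
            f"feature count {X_new.shape[1]} does not match training "
            f"({model.X_scaled.shape[1]})"
        )
    Xs = (X_new - model.mean) / model.scale
    Kx = kernel_matrix(Xs, model.X_scaled, model.gamma)
    return Kx @ model.beta + model.b


def dual_objective(K: np.ndarray, y: np.ndarray, beta: np.ndarray,
                   epsilon: float) -> float:
    """Dual objective (maximization form) at support coefficients ``beta``.

    W(beta) = -1/2 beta' K beta + y' beta - eps * ||beta||_1, using the
    optimality identity a_i * a_i* = 0.
    """
    beta = np.asarray(beta, dtype=float)
    return float(-0.5 * beta @ K @ beta + y @ beta
                 - epsilon * np.abs(beta).sum())


@dataclass
class GaConfig:
    """Genetic-algorithm settings for (C, gamma) tuning.

    Defaults mirror the study conditions: C searched on [0, 1000], gamma on
    [0, 10], 5-fold cross-validation fitness, at most 200 generations with a
    population of 20, and epsilon fixed at 0.001.  The C = 0 boundary is
    clamped to 1e-6 when candidates are evaluated (C = 0 is degenerate).
    """

    c_range: tuple = (0.0, 1000.0)
    gamma_range: tuple = (0.0, 10.0)
    folds: int = 5
    generations: int = 200
    population: int = 20
    epsilon: float = 0.001
    seed: int = 0
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_sigma_frac: float = 0.05
    tournament_size: int = 2
    elitism: int = 1

    def __post_init__(self):
        if self.c_range[1] <= self.c_range[0] or self.gamma_range[1] <= self.gamma_range[0]:
            raise ValueError("empty search range")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.population % 2:
            raise ValueError("population must be even")


def _fold_indices(n: int, m: int, rng: np.random.Generator) -> list:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, m)]


def cv_mse(X, y, C, gamma, epsilon, folds) -> float:
    """Mean held-out squared error of train_svr over the given folds."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    errs = []
    for held in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[held] = False
        model = train_svr(X[mask], y[mask], C=C, gamma=gamma, epsilon=epsilon)
        pred = predict_svr(model, X[held])
        errs.append(float(np.mean((pred - y[held]) ** 2)))
    return float(np.mean(errs))


def ga_optimize(X, y, cfg: GaConfig) -> tuple:
    """Tune (C, gamma) by a real-coded GA minimizing m-fold CV error.

    Tournament selection (size 2), blend crossover, Gaussian mutation with
    sigma at 5% of each range, elitism of one.  Fold assignment and all GA
    randomness derive from ``cfg.seed``, so runs are reproducible.

    Returns ``(C_best, gamma_best, per-generation best fitness history)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    folds = _fold_indices(len(y), cfg.folds, rng)
    c_lo, c_hi = cfg.c_range
    g_lo, g_hi = cfg.gamma_range

    def clip(ind):
        return (min(max(ind[0], c_lo), c_hi), min(max(ind[1], g_lo), g_hi))

    def fitness(ind):
        c = max(ind[0], 1e-6)
        return cv_mse(X, y, c, ind[1], cfg.epsilon, folds)

    pop = [(rng.uniform(c_lo, c_hi), rng.uniform(g_lo, g_hi))
           for _ in range(cfg.population)]
    fits = [fitness(ind) for ind in pop]
    best_idx = int(np.argmin(fits))
    best, best_fit = pop[best_idx], fits[best_idx]
    history = [best_fit]

    for _gen in range(cfg.generations):
        children = [best]  # elitism of one
        while len(children) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, cfg.tournament_size)
                parents.append(pop[min(contenders, key=lambda i: fits[i])])
            p1, p2 = parents
            if rng.random() < cfg.crossover_rate:
                lam = rng.random()
                c1 = (lam * p1[0] + (1 - lam) * p2[0],
                      lam * p1[1] + (1 - lam) * p2[1])
                c2 = ((1 - lam) * p1[0] + lam * p2[0],
                      (1 - lam) * p1[1] + lam * p2[1])
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if len(children) >= cfg.population:
                    break
                child = list(child)
                if rng.random() < cfg.mutation_rate:
                    child[0] += rng.normal(0.0, cfg.mutation_sigma_frac * (c_hi - c_lo))
                if rng.random() < cfg.mutation_rate:
                    child[1] += rng.normal(0.0, cfg.mutation_sigma_frac * (g_hi - g_lo))
                children.append(clip(tuple(child)))
        pop = children
        fits = [fitness(ind) for ind in pop]
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best, best_fit = pop[gen_best], fits[gen_best]
        history.append(best_fit)
    return max(best[0], 1e-6), best[1], history
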