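"""Independent oracles used by the test suite.

Each oracle is coded directly from the mathematical statement of the
quantity it checks, sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def nipals_pls1_oracle(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Textbook NIPALS PLS1 regression vector on centered data.

    Straight transcription of the algorithm: for each component,
    w = X'y normalised, t = Xw, p = X't / t't, q = y't / t't, deflate
    X and y; finally b = W (P'W)^-1 q.  Written with explicit loops.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n, p = X.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    for a in range(k):
        w = np.zeros(p)
        for j in range(p):
            for i in range(n):
                w[j] += X[i, j] * y[i]
        w = w / np.sqrt(np.sum(w * w))
        t = np.zeros(n)
        for i in range(n):
            for j in range(p):
                t[i] += X[i, j] * w[j]
        tt = np.sum(t * t)
        pvec = np.zeros(p)
        for j in range(p):
            for i in range(n):
                pvec[j] += X[i, j] * t[i]
            pvec[j] /= tt
        qa = np.sum(y * t) / tt
        for i in range(n):
            for j in range(p):
                X[i, j] -= t[i] * pvec[j]
            y[i] -= qa * t[i]
        W[:, a], P[:, a], q[a] = w, pvec, qa
    return W @ np.linalg.solve(P.T @ W, q)


def min_norm_lstsq(Xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares solution via the pseudoinverse."""
    return np.linalg.pinv(Xc) @ yc


def mc_f_lower_tail_p(f_obs: float, df1: int, df2: int, n_draws: int, seed: int):
    """Monte-Carlo estimate of P(F < f_obs) for F(df1, df2), with its SD.

    Simulates the variance-ratio statistic from first principles as a
    ratio of scaled chi-square draws.
    """
    rng = np.random.default_rng(seed)
    num = rng.chisquare(df1, n_draws) / df1
    den = rng.chisquare(df2, n_draws) / df2
    p = float(np.mean(num / den < f_obs))
    sd = float(np.sqrt(max(p * (1 - p), 1e-12) / n_draws))
    return p, sd


def permutation_mean_test_p(a: np.ndarray, b: np.ndarray, n_shuffles: int, seed: int) -> float:
    """Two-sided permutation p-value for a difference in means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= obs - 1e-12:
            count += 1
    return count / n_shuffles


def brute_force_argmax(values: np.ndarray, axis: np.ndarray, low: float, high: float) -> float:
    """Axis location of the maximum of `values` restricted to [low, high]."""
    best_v, best_x = -np.inf, None
    for x, v in zip(axis, values):
        if low <= x <= high and v > best_v:
            best_v, best_x = v, x
    return best_x
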