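"""Independent brute-force oracles used only by the test suite.

Each oracle solves the same problem as the package by a deliberately
different route (dense search, explicit normal equations, step-by-step
loops) so agreement is evidence of correctness, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def procrustes_residual_bruteforce(target: np.ndarray, moving: np.ndarray,
                                   n_grid: int = 2000, seed: int = 0) -> float:
    """Min residual ||A - B R'|| over proper rotations by dense random
    search over SO(3) followed by local refinement in rotation-vector
    coordinates.  Inputs are centered to unit centroid size first.
    """

    def normalize(points):
        centered = points - points.mean(axis=0)
        return centered / np.sqrt((centered ** 2).sum())

    a = normalize(np.asarray(target, dtype=float))
    b = normalize(np.asarray(moving, dtype=float))

    def residual(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((a - b @ rot.T) ** 2).sum())

    rng = np.random.default_rng(seed)
    candidates = Rotation.random(n_grid, random_state=rng).as_rotvec()
    values = np.array([residual(v) for v in candidates])
    order = np.argsort(values)
    best = np.inf
    for idx in order[:5]:
        out = minimize(residual, candidates[idx], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, out.fun)
    return float(best)


def ancova_normal_equations(values, sex, height, age):
    """Explicit (X'X)^-1 X'y solution of value ~ 1 + male + height + age.

    Returns (adj_mean_male, adj_mean_female, p_sex, ms_within) with the
    sex p from the t distribution on n - 4 df.
    """
    y = np.asarray(values, dtype=float)
    male = (np.asarray(sex) == "M").astype(float)
    h = np.asarray(height, dtype=float)
    a = np.asarray(age, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), male, h, a])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = n - 4
    ms = resid @ resid / df
    se_sex = np.sqrt(ms * xtx_inv[1, 1])
    t = beta[1] / se_sex
    p = 2 * stats.t.sf(abs(t), df)
    adj_f = beta[0] + beta[2] * h.mean() + beta[3] * a.mean()
    adj_m = adj_f + beta[1]
    return float(adj_m), float(adj_f), float(p), float(ms)


def classic_cohens_d(values, sex):
    """Textbook pooled-SD Cohen's d, males minus females."""
    y = np.asarray(values, dtype=float)
    male = np.asarray(sex) == "M"
    a, b = y[male], y[~male]
    n1, n2 = len(a), len(b)
    pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    return float((a.mean() - b.mean()) / pooled)


def welch_t_p(a, b):
    """Welch two-sample two-sided p from the textbook formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return float(2 * stats.t.sf(abs(t), df))


def loo_classification_oracle(X, y):
    """Step-by-step leave-one-out two-group linear discriminant.

    Re-derives means, pooled covariance (pseudo-inverse), weight vector,
    midpoint threshold, and held-out classification with explicit loops.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    predictions = []
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        Xi, yi = X[mask], y[mask]
        mean_m = Xi[yi == "M"].mean(axis=0)
        mean_f = Xi[yi == "F"].mean(axis=0)
        centered = np.concatenate([
            Xi[yi == "M"] - mean_m, Xi[yi == "F"] - mean_f
        ])
        pooled = centered.T @ centered / (len(yi) - 2)
        w = np.linalg.pinv(pooled, rcond=1e-10, hermitian=True) @ (mean_m - mean_f)
        threshold = 0.5 * (mean_m @ w + mean_f @ w)
        predictions.append("M" if X[i] @ w > threshold else "F")
    return np.array(predictions)
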