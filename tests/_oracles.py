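"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid scipy.optimize so they cannot share a failure mode
with the solver they check.
"""

import numpy as np


def grid_nnls_min(K: np.ndarray, y: np.ndarray, step: float = 0.01, box: float = 3.0) -> float:
    """Exact minimum of ||K w - y||^2 over the non-negative grid
    {0, step, ..., box}^n_classes, for n_classes in {2, 3}.

    For 3 classes the third coordinate is minimized analytically per grid
    pair: the objective is a convex parabola in w3, so the grid optimum is
    the rounded-and-clipped vertex (floor and ceil both checked).
    """
    K = np.asarray(K, float)
    y = np.asarray(y, float)
    n = K.shape[1]
    G = K.T @ K
    b = K.T @ y
    c0 = float(y @ y)
    grid = np.arange(0.0, box + step / 2, step)

    if n == 2:
        w1, w2 = np.meshgrid(grid, grid, indexing="ij")
        f = (
            G[0, 0] * w1**2 + G[1, 1] * w2**2 + 2 * G[0, 1] * w1 * w2
            - 2 * b[0] * w1 - 2 * b[1] * w2 + c0
        )
        return float(f.min())
    if n != 3:
        raise ValueError("oracle supports 2 or 3 classes")

    w1, w2 = np.meshgrid(grid, grid, indexing="ij")
    # f(w3 | w1,w2) = G33 w3^2 + 2(G13 w1 + G23 w2 - b3) w3 + f2(w1,w2)
    lin = G[0, 2] * w1 + G[1, 2] * w2 - b[2]
    f2 = (
        G[0, 0] * w1**2 + G[1, 1] * w2**2 + 2 * G[0, 1] * w1 * w2
        - 2 * b[0] * w1 - 2 * b[1] * w2 + c0
    )
    if G[2, 2] <= 0:
        cands = [np.zeros_like(w1), np.full_like(w1, box)]
    else:
        vertex = -lin / G[2, 2]
        lo = np.clip(np.floor(vertex / step) * step, 0.0, box)
        hi = np.clip(np.ceil(vertex / step) * step, 0.0, box)
        cands = [lo, hi]
    best = np.inf
    for w3 in cands:
        f = G[2, 2] * w3**2 + 2 * lin * w3 + f2
        best = min(best, float(f.min()))
    return best


def simplex_min_residual(k_a: np.ndarray, k_b: np.ndarray, y: np.ndarray,
                         step: float = 1e-3) -> float:
    """Min of ||a*k_a + (1-a)*k_b - y||^2 over a in {0, step, ..., 1}."""
    a = np.arange(0.0, 1.0 + step / 2, step)[:, None]
    resid = a * k_a[None, :] + (1 - a) * k_b[None, :] - y[None, :]
    return float((resid**2).sum(axis=1).min())
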