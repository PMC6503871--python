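"""Independent reference implementations used as test oracles.

These deliberately take the slow, obvious route (per-probe loops, grid
search) and share no code with the library paths they check.
"""

import numpy as np


def naive_sem_mask(values, quantile_method="linear", multiplier=3.0):
    """Two-loop SEM caller: per-probe quantiles and fence comparison
    recomputed independently of the vectorized implementation."""
    n, m = values.shape
    mask = np.zeros((n, m), dtype=bool)
    for j in range(m):
        col = values[:, j]
        col_ok = col[~np.isnan(col)]
        q1 = np.quantile(col_ok, 0.25, method=quantile_method)
        q3 = np.quantile(col_ok, 0.75, method=quantile_method)
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        for i in range(n):
            v = col[i]
            if not np.isnan(v) and (v < lo or v > hi):
                mask[i, j] = True
    return mask


def grid_search_reml(betas, ses, n_grid=10_001):
    """Grid-search REML oracle: coarse 10,001-point grid over [0, tau2_max]
    followed by a 10,001-point local refinement around the best coarse
    point (a single coarse grid cannot certify 1e-6 agreement)."""
    beta = np.asarray(betas, float)
    v = np.asarray(ses, float) ** 2
    tau2_max = 10.0 * v.max() * len(beta)

    def ll_vec(grid):
        V = v[None, :] + grid[:, None]
        w = 1.0 / V
        bh = (w * beta).sum(1) / w.sum(1)
        return (-0.5 * np.log(V).sum(1) - 0.5 * np.log(w.sum(1))
                - 0.5 * (w * (beta - bh[:, None]) ** 2).sum(1))

    grid = np.linspace(0.0, tau2_max, n_grid)
    best = grid[np.argmax(ll_vec(grid))]
    step = grid[1] - grid[0]
    fine = np.linspace(max(0.0, best - step), best + step, n_grid)
    tau2 = fine[np.argmax(ll_vec(fine))]
    w = 1.0 / (v + tau2)
    return tau2, float((w * beta).sum() / w.sum())
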