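"""Independent reference implementations used to check the pipeline.

These deliberately avoid the code paths they validate: the 4PL oracle
is a dense grid search with a closed-form linear solve for the
asymptotes, the Manhattan oracle a double loop, and the AUC oracle a
per-segment closed-form integral.
"""

from __future__ import annotations

import numpy as np


def grid_fit_4pl(
    x,
    y,
    log_ec50_grid=None,
    hill_grid=None,
):
    """Brute-force 4PL fit: grid over (log_ec50, hill), exact solve for
    (bottom, top).

    For fixed shape s(x) = 1 / (1 + 10**((le - x) h)) the model
    ``bottom (1 - s) + top s`` is linear in (bottom, top), so the
    optimal asymptotes come from a 2x2 least-squares solve per grid
    node.  Returns (rss, bottom, top, log_ec50, hill) of the best node.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if log_ec50_grid is None:
        log_ec50_grid = np.linspace(x.min() - 1.0, x.max() + 1.0, 221)
    if hill_grid is None:
        hill_grid = np.concatenate(
            [np.linspace(-4.0, -0.02, 200), np.linspace(0.02, 4.0, 200)]
        )
    best = (np.inf, np.nan, np.nan, np.nan, np.nan)
    for le in log_ec50_grid:
        for h in hill_grid:
            z = np.clip((le - x) * h, -50.0, 50.0)
            s = 1.0 / (1.0 + 10.0 ** z)
            design = np.column_stack([1.0 - s, s])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            rss = float(resid @ resid)
            if rss < best[0]:
                best = (rss, float(coef[0]), float(coef[1]), float(le), float(h))
    return best


def manhattan_distances(matrix: np.ndarray) -> np.ndarray:
    """Pairwise city-block distances via an explicit double loop."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total = 0.0
            for p in range(matrix.shape[1]):
                total += abs(matrix[i, p] - matrix[j, p])
            out[i, j] = total
    return out


def piecewise_linear_auc(t, y) -> float:
    """Closed-form integral of the linear interpolant, segment by segment."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    total = 0.0
    for i in range(len(t) - 1):
        total += (t[i + 1] - t[i]) * (y[i] + y[i + 1]) / 2.0
    return total
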