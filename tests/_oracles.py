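"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: OLS is solved through
the normal equations with explicit matrix inversion, and the greedy stepwise
oracle exhaustively refits every augmented model at each step.
"""

from __future__ import annotations

import numpy as np


def ols_normal_equations(y, X):
    """(beta_with_intercept, r2, adj_r2) via the normal equations."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    beta = np.linalg.inv(design.T @ design) @ design.T @ y
    resid = y - design @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return beta, r2, adj


def greedy_stepwise_oracle(data, variables, y, gain=0.01):
    """Exhaustive greedy forward selection under sign constraints.

    ``data`` is a DataFrame of candidate columns, ``variables`` the list of
    VariableDef objects. Returns the selection path (forced first), mirroring
    the published protocol: at each step refit every remaining candidate
    added alone, keep only sign-eligible candidates (entrant and all
    non-forced incumbents), admit the largest adjusted-R² gain >= ``gain``.
    Ties break on the lexicographically smallest name.
    """
    y = np.asarray(y, dtype=float)
    defs = {v.name: v for v in variables}
    forced = [v.name for v in variables if v.forced]
    remaining = sorted(v.name for v in variables if not v.forced)
    current = list(forced)
    if current:
        _, _, cur_adj = ols_normal_equations(y, data[current].to_numpy())
    else:
        cur_adj = 0.0
    while remaining:
        best, best_gain = None, -np.inf
        for name in remaining:  # lexicographic order; strict > keeps first tie
            col = data[name].to_numpy(dtype=float)
            if np.ptp(col) == 0.0:
                continue
            trial = current + [name]
            X = data[trial].to_numpy(dtype=float)
            design = np.column_stack([np.ones(len(y)), X])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            beta, _, adj = ols_normal_equations(y, X)
            coefs = dict(zip(trial, beta[1:]))
            eligible = all(
                np.sign(coefs[t]) == (1 if defs[t].direction == "positive" else -1)
                for t in trial
                if not defs[t].forced
            )
            if not eligible:
                continue
            g = adj - cur_adj
            if g > best_gain:
                best, best_gain = name, g
        if best is None or best_gain < gain:
            break
        current.append(best)
        remaining.remove(best)
        cur_adj += best_gain
    return current


def point_segment_distance_scalar(px, py, x1, y1, x2, y2):
    """Plain scalar point-to-segment distance (no vectorization tricks)."""
    dx, dy = x2 - x1, y2 - y1
    a = dx * dx + dy * dy
    if a == 0.0:
        return np.hypot(px - x1, py - y1)
    t = ((px - x1) * dx + (py - y1) * dy) / a
    t = min(1.0, max(0.0, t))
    return np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))
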