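"""Penalized exact change-point partitioning.

Two segment cost models are provided: piecewise-linear (for free-end
trajectories, where each segment is an OLS line) and piecewise-constant
(for photobleaching intensity traces, where each segment is a level).
Both use O(n^2) optimal partitioning with a per-segment BIC-style
penalty; trajectory and trace lengths here are a few hundred frames, so
the quadratic dynamic program is exact and fast.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mad_sigma", "piecewise_linear_breakpoints", "piecewise_constant_breakpoints"]

_MAD_TO_SD = 1.4826


def mad_sigma(y: np.ndarray, order: int = 1) -> float:
    """Noise SD estimated from the MAD of ``order``-th differences.

    First differences suit piecewise-constant signals (level changes are
    a sparse minority); second differences additionally cancel linear
    trends, which is what a trajectory moving for most of the record
    needs.  The sqrt(2) / sqrt(6) factors undo the variance inflation of
    differencing i.i.d. noise once or twice.
    """
    d = np.diff(np.asarray(y, dtype=float), n=order)
    if d.size == 0:
        return 0.0
    scale = np.sqrt(2.0) if order == 1 else np.sqrt(6.0)
    return _MAD_TO_SD * float(np.median(np.abs(d - np.median(d)))) / scale


def _linear_cost_matrix(x: np.ndarray, y: np.ndarray, min_size: int) -> np.ndarray:
    """RSS of an OLS line on every window [i, j); inf where j-i < min_size."""
    n = len(y)
    z = np.zeros(1)
    c1 = np.concatenate([z, np.cumsum(np.ones(n))])
    cx = np.concatenate([z, np.cumsum(x)])
    cy = np.concatenate([z, np.cumsum(y)])
    cxx = np.concatenate([z, np.cumsum(x * x)])
    cxy = np.concatenate([z, np.cumsum(x * y)])
    cyy = np.concatenate([z, np.cumsum(y * y)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        j = np.arange(i + min_size, n + 1)
        if j.size == 0:
            continue
        m = c1[j] - c1[i]
        sx = cx[j] - cx[i]
        sy = cy[j] - cy[i]
        sxx = (cxx[j] - cxx[i]) - sx * sx / m
        sxy = (cxy[j] - cxy[i]) - sx * sy / m
        syy = (cyy[j] - cyy[i]) - sy * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = syy - np.where(sxx > 0, sxy * sxy / np.maximum(sxx, 1e-300), 0.0)
        cost[i, j] = np.maximum(rss, 0.0)
    return cost

def _constant_cost_matrix(y: np.ndarray, min_size: int) -> np.ndarray:
    n = len(y)
    z = np.zeros(1)
    cy = np.concatenate([z, np.cumsum(y)])
    cyy = np.concatenate([z, np.cumsum(y * y)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        j = np.arange(i + min_size, n + 1)
        if j.size == 0:
            continue
        m = j - i
        rss = (cyy[j] - cyy[i]) - (cy[j] - cy[i]) ** 2 / m
        cost[i, j] = np.maximum(rss, 0.0)
    return cost


def _optimal_partition(cost: np.ndarray, penalty: float) -> list[int]:
    """Minimize sum of segment costs + penalty per segment; returns interior breakpoints."""
    n = cost.shape[0] - 1
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        cand = f[:j] + cost[:j, j] + penalty
        best = float(np.min(cand))
        # ties resolved toward the largest predecessor: the shared boundary
        # sample of a continuous signal then attaches to the earlier segment
        tol = min(1e-9 * (1.0 + abs(best)), 0.01 * penalty)
        i = int(np.flatnonzero(cand <= best + tol)[-1])
        f[j] = cand[i]
        last[j] = i
    bkps: list[int] = []
    j = n
    while j > 0:
        i = last[j]
        if i > 0:
            bkps.append(i)
        j = i
    return sorted(bkps)


def _sigma_floor(y: np.ndarray, sigma: float | None, order: int = 1) -> float:
    # keep the penalty strictly positive on noiseless input so ties
    # resolve toward the fewest segments
    s = mad_sigma(y, order=order) if sigma is None else float(sigma)
    scale = float(np.ptp(y)) if len(y) else 1.0
    return max(s, 1e-6 * max(scale, 1.0), 1e-12)


def piecewise_linear_breakpoints(
    x: np.ndarray,
    y: np.ndarray,
    min_size: int = 3,
    penalty_scale: float = 3.0,
    sigma: float | None = None,
) -> list[int]:
    """Interior breakpoints of the BIC-penalized piecewise-linear fit.

    The per-segment penalty is ``penalty_scale * sigma^2 * log(n)``
    (slope, intercept and the breakpoint location itself count as free
    parameters, hence the default scale of 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_size:
        return []
    s = _sigma_floor(y, sigma, order=2)
    return _optimal_partition(_linear_cost_matrix(x, y, min_size),
                              penalty_scale * s * s * np.log(n))


def piecewise_constant_breakpoints(
    y: np.ndarray,
    min_size: int = 2,
    penalty_scale: float = 2.0,
    sigma: float | None = None,
) -> list[int]:
    """Interior breakpoints of the BIC-penalized piecewise-constant fit."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_size:
        return []
    s = _sigma_floor(y, sigma)
    return _optimal_partition(_constant_cost_matrix(y, min_size),
                              penalty_scale * s * s * np.log(n))
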