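"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (explicit loops, O(n*w)) so they share no code
with the library paths they verify.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_opening(x: np.ndarray, half_window: int) -> np.ndarray:
    """Grayscale opening (erosion then dilation) with truncated windows."""
    n = len(x)
    eroded = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        eroded[i] = min(x[lo:hi])
    opened = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        opened[i] = max(eroded[lo:hi])
    return opened


def brute_opening_fast(x: np.ndarray, half_window: int) -> np.ndarray:
    """Padded sliding-window variant of the opening oracle (for big inputs).

    Edge replication makes the truncated window and the padded window agree,
    because duplicated edge values never change a min or max.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    w = half_window
    pad = np.pad(x, w, mode="edge")
    eroded = sliding_window_view(pad, 2 * w + 1).min(axis=1)
    pad2 = np.pad(eroded, w, mode="edge")
    return sliding_window_view(pad2, 2 * w + 1).max(axis=1)


def brute_peak_indices(x: np.ndarray, half_window: int, threshold: float) -> list[int]:
    """Windowed-argmax peak oracle: strict local maxima above a threshold."""
    n = len(x)
    out = []
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        window = x[lo:hi]
        if x[i] <= 0 or x[i] < threshold:
            continue
        if all(x[i] > v for j, v in zip(range(lo, hi), window) if j != i):
            out.append(i)
    return out


def brute_mannwhitney_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating rank assignments.

    Requires tie-free pooled data.  Enumerates every C(nx+ny, nx) way of
    assigning the pooled ranks to group x and counts assignments whose U is
    at least as extreme (min(U, nx*ny - U) <= observed) as the observed one.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    stat_obs = min(u_obs, nx * ny - u_obs)
    total = extreme = 0
    for combo in combinations(range(nx + ny), nx):
        r = sum(sorted(range(1, nx + ny + 1))[i] for i in combo)
        u = r - nx * (nx + 1) / 2
        if min(u, nx * ny - u) <= stat_obs:
            extreme += 1
        total += 1
    return extreme / total
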