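"""Numba-compiled hot loops: footrule distances and the Metropolis chain
over permutations used both for sampling from a Mallows law and for
estimating the partition function by thermodynamic integration.

Permutations are rank vectors: entry i is the rank (1..n) of item i.
The Metropolis kernel never needs the normalizing constant, which is what
makes it usable for estimating that constant.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def footrule(r, s):
    d = 0
    for i in range(r.shape[0]):
        d += abs(r[i] - s[i])
    return d


@njit(cache=True)
def _window(rank, L, n):
    # number of candidate new ranks for an item currently at `rank`
    lo = rank - L
    if lo < 1:
        lo = 1
    hi = rank + L
    if hi > n:
        hi = n
    return hi - lo


@njit(cache=True)
def _ls_step(r, rho, alpha, L, n):
    """One leap-and-shift Metropolis step targeting exp(-alpha*d(r,rho)/n).

    Mutates ``r`` in place on acceptance; returns the (possibly unchanged)
    current footrule distance increment (0 if rejected).
    """
    u = np.random.randint(0, n)
    cur = r[u]
    lo = cur - L
    if lo < 1:
        lo = 1
    hi = cur + L
    if hi > n:
        hi = n
    new = lo + np.random.randint(0, hi - lo)
    if new >= cur:
        new += 1
    # distance change for the moved item plus the shifted block
    delta = abs(new - rho[u]) - abs(cur - rho[u])
    if new > cur:
        for i in range(n):
            ri = r[i]
            if cur < ri <= new and i != u:
                delta += abs(ri - 1 - rho[i]) - abs(ri - rho[i])
    else:
        for i in range(n):
            ri = r[i]
            if new <= ri < cur and i != u:
                delta += abs(ri + 1 - rho[i]) - abs(ri - rho[i])
    leap = abs(new - cur)
    if leap >= 2:
        log_ratio = np.log(_window(cur, L, n)) - np.log(_window(new, L, n))
    else:
        log_ratio = 0.0  # adjacent swap: forward/backward probabilities match
    if np.log(np.random.random()) < -alpha * delta / n + log_ratio:
        # apply the shift
        if new > cur:
            for i in range(n):
                if cur < r[i] <= new and i != u:
                    r[i] -= 1
        else:
            for i in range(n):
                if new <= r[i] < cur and i != u:
                    r[i] += 1
        r[u] = new
        return delta
    return 0


@njit(cache=True)
def sample_chain(rho, alpha, L, burn_in, thin, m, seed):
    """Draw m permutations from Mallows(rho, alpha) via leap-and-shift MCMC."""
    np.random.seed(seed)
    n = rho.shape[0]
    r = rho.copy()
    out = np.empty((m, n), dtype=rho.dtype)
    for _ in range(burn_in):
        _ls_step(r, rho, alpha, L, n)
    for k in range(m):
        for _ in range(thin):
            _ls_step(r, rho, alpha, L, n)
        out[k] = r
    return out


@njit(cache=True)
def mean_distance_profile(n, alpha_grid, L, steps_per_point, discard, seed):
    """E_alpha[d(R, rho)] under Mallows at each grid alpha, warm-started.

    The chain at grid point k starts from the final state of point k-1;
    the first ``discard`` steps at each point are dropped as re-adaptation.
    Returns the vector of mean footrule distances (grid must be increasing).
    """
    np.random.seed(seed)
    rho = np.arange(1, n + 1).astype(np.int64)
    r = rho.copy()
    # start from a uniform draw (alpha grid begins at 0)
    for _ in range(50 * n):
        _ls_step(r, rho, 0.0, L, n)
    d = footrule(r, rho)
    out = np.empty(alpha_grid.shape[0])
    for k in range(alpha_grid.shape[0]):
        a = alpha_grid[k]
        for _ in range(discard):
            d += _ls_step(r, rho, a, L, n)
        acc = 0.0
        for _ in range(steps_per_point):
            d += _ls_step(r, rho, a, L, n)
            acc += d
        out[k] = acc / steps_per_point
    return out
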