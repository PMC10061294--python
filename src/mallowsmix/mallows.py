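"""The Mallows model over permutations with the Spearman footrule distance.

The model places probability exp(-alpha*d(r, rho)/n) / Z_n(alpha) on every
permutation r of 1..n, where rho is the consensus ranking (location), alpha
the scale (precision-like: larger alpha concentrates mass near rho), and
d the footrule distance sum_i |r_i - s_i|.  The alpha/n scaling in the
exponent is part of the model definition here, so reported alpha values are
comparable across n.

The footrule is right-invariant, so the partition function Z_n depends on
alpha only.  For small n (default cap 8) Z_n is computed exactly from the
enumerated distribution of footrule distances; for larger n it is estimated
by thermodynamic integration of the identity

    d log Z_n / d alpha = -E_alpha[d]/n,

with E_alpha[d] estimated by the Metropolis sampler (which needs no
normalizing constant) on a dense alpha grid, and the cumulative integral
anchored at log Z_n(0) = log n!.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import gammaln, logsumexp

from . import _kernels

__all__ = [
    "MallowsParams",
    "DistanceHistogram",
    "PartitionTable",
    "footrule_distance",
    "exact_distance_counts",
    "log_partition",
    "mallows_log_pmf",
    "sample_mallows",
    "ENUM_CAP",
]

ENUM_CAP = 8  # n! enumeration is cheap up to here (8! = 40320)


def _as_perm(r, name: str = "permutation") -> np.ndarray:
    r = np.asarray(r, dtype=np.int64)
    if r.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    n = r.shape[0]
    if not np.array_equal(np.sort(r), np.arange(1, n + 1)):
        raise ValueError(f"{name} is not a permutation of 1..{n}")
    return r


@dataclass
class MallowsParams:
    """Consensus ranking rho (permutation of 1..n) and scale alpha >= 0."""

    rho: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.rho = _as_perm(self.rho, "rho")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def n(self) -> int:
        return self.rho.shape[0]


@dataclass
class DistanceHistogram:
    """Counts of permutations of 1..n at each footrule distance from a
    fixed reference; by right-invariance the reference does not matter."""

    n: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != math.factorial(self.n):
            raise ValueError("histogram counts must sum to n!")
        dmax = self.n * self.n // 2
        for d in self.counts:
            if d % 2 or d < 0 or d > dmax:
                raise ValueError(f"invalid footrule distance key: {d}")


@dataclass
class PartitionTable:
    """log Z_n(alpha) on an alpha grid, exact (from a distance histogram)
    or estimated by thermodynamic integration."""

    n: int
    alpha_grid: np.ndarray
    log_z: np.ndarray
    method: str  # "exact-enumeration" | "thermodynamic-integration"
    histogram: DistanceHistogram | None = None
    mc_error: np.ndarray | None = None
    _interp: PchipInterpolator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        self.log_z = np.asarray(self.log_z, dtype=float)
        if self.alpha_grid.shape != self.log_z.shape:
            raise ValueError("alpha_grid and log_z shapes differ")
        if np.any(np.diff(self.alpha_grid) <= 0) or self.alpha_grid[0] < 0:
            raise ValueError("alpha_grid must be increasing and non-negative")
        if np.any(np.diff(self.log_z) > 1e-9):
            raise ValueError("log_z must be non-increasing in alpha")

    # -- construction -----------------------------------------------------
    @classmethod
    def exact(cls, n: int, alpha_max: float = 50.0, n_grid: int = 201,
              cap: int = ENUM_CAP) -> "PartitionTable":
        hist = exact_distance_counts(n, cap=cap)
        grid = np.linspace(0.0, alpha_max, n_grid)
        log_z = np.array([_log_z_from_hist(a, hist) for a in grid])
        return cls(n=n, alpha_grid=grid, log_z=log_z,
                   method="exact-enumeration", histogram=hist)

    @classmethod
    def estimate(cls, n: int, alpha_max: float = 50.0, n_grid: int = 201,
                 seed: int = 0, steps_per_point: int = 20000,
                 leap: int | None = None) -> "PartitionTable":
        """Thermodynamic-integration estimate for n beyond the enumeration cap."""
        grid = np.linspace(0.0, alpha_max, n_grid)
        L = leap if leap is not None else max(1, round(n / 5))
        mean_d = _kernels.mean_distance_profile(
            n, grid, L, steps_per_point, steps_per_point // 4,
            int(seed) % (2**31 - 1) + 1,
        )
        # anchor the integrand at the exact uniform mean E_0[d] = (n^2-1)/3
        mean_d[0] = (n * n - 1) / 3.0
        log_z = gammaln(n + 1) - np.concatenate(
            ([0.0], np.cumsum((mean_d[1:] + mean_d[:-1]) / 2 * np.diff(grid)))
        ) / n
        log_z = np.minimum.accumulate(log_z)  # enforce monotonicity
        return cls(n=n, alpha_grid=grid, log_z=log_z,
                   method="thermodynamic-integration")

    @classmethod
    def build(cls, n: int, alpha_max: float = 50.0, seed: int = 0,
              cap: int = ENUM_CAP, **kwargs) -> "PartitionTable":
        """Exact when n <= cap, estimated otherwise."""
        if n <= cap:
            return cls.exact(n, alpha_max=alpha_max)
        return cls.estimate(n, alpha_max=alpha_max, seed=seed, **kwargs)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        df = pd.DataFrame({"alpha": self.alpha_grid, "log_z": self.log_z})
        with open(path, "w") as fh:
            fh.write(f"# n={self.n} method={self.method}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "PartitionTable":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split())
            df = pd.read_csv(fh, sep="\t")
        return cls(n=int(meta["n"]), alpha_grid=df["alpha"].to_numpy(),
                   log_z=df["log_z"].to_numpy(), method=meta["method"])

    # -- evaluation --------------------------------------------------------
    def __call__(self, alpha: float) -> float:
        return log_partition(alpha, self.n, self)


def footrule_distance(r, s) -> int:
    """Spearman footrule sum_i |r_i - s_i| between two permutations of 1..n."""
    r = _as_perm(r, "r")
    s = _as_perm(s, "s")
    if r.shape[0] != s.shape[0]:
        raise ValueError("permutations have different lengths")
    return int(_kernels.footrule(r, s))


def _all_perms(n: int) -> np.ndarray:
    return np.array(list(permutations(range(1, n + 1))), dtype=np.int64)


def exact_distance_counts(n: int, cap: int = ENUM_CAP) -> DistanceHistogram:
    """Exhaustive distribution of footrule distances from the identity."""
    if n > cap:
        raise ValueError(
            f"n={n} exceeds enumeration cap {cap}; use PartitionTable.estimate"
        )
    perms = _all_perms(n)
    d = np.abs(perms - np.arange(1, n + 1)).sum(axis=1)
    vals, counts = np.unique(d, return_counts=True)
    return DistanceHistogram(n=n, counts={int(v): int(c) for v, c in zip(vals, counts)})


def _log_z_from_hist(alpha: float, hist: DistanceHistogram) -> float:
    arrays = getattr(hist, "_arrays", None)
    if arrays is None:
        d = np.array(sorted(hist.counts))
        c = np.array([hist.counts[int(k)] for k in d], dtype=float)
        arrays = hist._arrays = (d, c)
    d, c = arrays
    return float(logsumexp(-alpha * d / hist.n, b=c))


def log_partition(alpha: float, n: int, table: PartitionTable) -> float:
    """log Z_n(alpha); exact from the histogram, or monotone interpolation
    on the estimated grid.  Extrapolation beyond the grid is refused."""
    if table.n != n:
        raise ValueError(f"table is for n={table.n}, not n={n}")
    if alpha < table.alpha_grid[0] - 1e-12 or alpha > table.alpha_grid[-1] + 1e-12:
        raise ValueError(
            f"alpha={alpha} outside table grid "
            f"[{table.alpha_grid[0]}, {table.alpha_grid[-1]}]"
        )
    if table.method == "exact-enumeration":
        return _log_z_from_hist(alpha, table.histogram)
    if table._interp is None:
        table._interp = PchipInterpolator(table.alpha_grid, table.log_z)
    return float(table._interp(alpha))


def mallows_log_pmf(r, params: MallowsParams, table: PartitionTable) -> float:
    """log P(r | rho, alpha) = -alpha*d(r, rho)/n - log Z_n(alpha)."""
    d = footrule_distance(r, params.rho)
    return -params.alpha * d / params.n - log_partition(params.alpha, params.n, table)


def sample_mallows(
    params: MallowsParams,
    m: int,
    seed: int,
    method: str = "auto",
    burn_in: int | None = None,
    thin: int | None = None,
    cap: int = ENUM_CAP,
) -> np.ndarray:
    """Draw m permutations from the Mallows law, as an (m, n) array.

    "exact-enum" enumerates P_n (n <= cap) and samples from the exact pmf;
    "mcmc" runs the leap-and-shift Metropolis chain (default burn-in 1000*n
    steps, thinning 10*n steps between draws so successive draws are close
    to independent).
    """
    n = params.n
    if method == "auto":
        method = "exact-enum" if n <= cap else "mcmc"
    if method == "exact-enum":
        if n > cap:
            raise ValueError(f"exact-enum requires n <= {cap}")
        perms = _all_perms(n)
        d = np.abs(perms - params.rho).sum(axis=1)
        w = np.exp(-params.alpha * (d - d.min()) / n)
        rng = np.random.default_rng(seed)
        idx = rng.choice(perms.shape[0], size=m, p=w / w.sum())
        return perms[idx]
    if method != "mcmc":
        raise ValueError(f"unknown method: {method!r}")
    burn_in = 1000 * n if burn_in is None else burn_in
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    thin = 10 * n if thin is None else thin
    L = max(1, round(n / 5))
    return _kernels.sample_chain(
        params.rho, float(params.alpha), L, burn_in, thin, m,
        int(seed) % (2**31 - 1) + 1,
    )
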