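"""Metropolis-Hastings MCMC for the C-component Mallows mixture.

Each cluster c carries a consensus ranking rho_c and a scale alpha_c; each
sample j carries a latent label z_j and the mixture has Dirichlet-weighted
components.  One sweep updates, in order: the labels z (Gibbs), the weights
(conjugate Dirichlet), every alpha_c (log-scale Gaussian random walk with
an exponential prior), and every rho_c (leap-and-shift proposals; the
partition function cancels because the footrule Z is free of rho).

Label switching is handled after the run by greedily matching every stored
iteration's clusters to a reference iteration (the one with the highest
log-likelihood), by minimal footrule distance between consensus rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_ranks import RankMatrix
from .mallows import PartitionTable, log_partition

__all__ = [
    "PriorSpec",
    "MixtureState",
    "PosteriorSamples",
    "leap_and_shift_propose",
    "update_assignments",
    "update_weights",
    "update_alpha",
    "update_rho",
    "run_mcmc",
    "relabel",
    "diagnostics",
]


@dataclass
class PriorSpec:
    """Hyperparameters and proposal tuning.

    alpha_prior_rate: rate of the exponential prior on each alpha_c.
    dirichlet_concentration: symmetric Dirichlet parameter on the weights.
    leap_size: leap-and-shift window half-width (None -> max(1, n/20)).
    alpha_proposal_sd: sd of the Gaussian random walk on log(alpha).
    rho_proposals_per_sweep: leap-and-shift proposals per cluster per sweep.
    """

    alpha_prior_rate: float = 0.1
    dirichlet_concentration: float = 10.0
    leap_size: int | None = None
    alpha_proposal_sd: float = 0.1
    rho_proposals_per_sweep: int = 1

    def __post_init__(self) -> None:
        if (self.alpha_prior_rate <= 0 or self.dirichlet_concentration <= 0
                or self.alpha_proposal_sd <= 0
                or self.rho_proposals_per_sweep < 1):
            raise ValueError("prior/proposal parameters must be strictly positive")
        if self.leap_size is not None and self.leap_size < 1:
            raise ValueError("leap_size must be >= 1")

    def leap(self, n: int) -> int:
        L = self.leap_size if self.leap_size is not None else max(1, round(n / 20))
        if L > n - 1:
            raise ValueError(f"leap_size {L} must be <= n-1 = {n - 1}")
        return L


@dataclass
class MixtureState:
    """One MCMC state: per-cluster (rho_c, alpha_c), labels z, weights."""

    rho: np.ndarray     # (C, n) rank vectors
    alpha: np.ndarray   # (C,)
    z: np.ndarray       # (N,) labels in 0..C-1
    weights: np.ndarray  # (C,) simplex

    def __post_init__(self) -> None:
        C, n = self.rho.shape
        expected = np.arange(1, n + 1)
        for c in range(C):
            if not np.array_equal(np.sort(self.rho[c]), expected):
                raise ValueError(f"rho[{c}] is not a permutation of 1..{n}")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if self.z.min() < 0 or self.z.max() >= C:
            raise ValueError("labels out of range")

    @property
    def C(self) -> int:
        return self.rho.shape[0]


@dataclass
class PosteriorSamples:
    """Stored post-burn-in iterations plus acceptance counters and config echo.

    Arrays are stacked over stored iterations T: rho (T, C, n),
    alpha (T, C), z (T, N), weights (T, C), log_lik (T,),
    within_distance (T,) = sum_j d(R_j, rho_{z_j}) at that iteration.
    """

    rho: np.ndarray
    alpha: np.ndarray
    z: np.ndarray
    weights: np.ndarray
    log_lik: np.ndarray
    within_distance: np.ndarray
    acceptance: dict
    config: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return self.rho.shape[0]

    @property
    def C(self) -> int:
        return self.rho.shape[1]

    @property
    def n(self) -> int:
        return self.rho.shape[2]


# ---------------------------------------------------------------------------
# proposals and single-parameter updates

def _window(rank: int, L: int, n: int) -> int:
    return min(n, rank + L) - max(1, rank - L)


def leap_and_shift_propose(rho: np.ndarray, L: int, rng) -> tuple[np.ndarray, float]:
    """Leap-and-shift proposal from a rank vector.

    Pick an item uniformly, move its rank to a uniformly chosen new value
    within +/-L (excluding the current one), and shift the intervening items
    by one.  Returns (proposal, log backward/forward proposal ratio).  For a
    leap of 1 the move is an adjacent swap generatable from either involved
    item and the ratio is exactly 0; for larger leaps it is the log ratio of
    the two window sizes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = rho.shape[0]
    if not 1 <= L <= n - 1:
        raise ValueError(f"leap size must be in [1, {n - 1}]")
    u = int(rng.integers(n))
    cur = int(rho[u])
    lo, hi = max(1, cur - L), min(n, cur + L)
    new = lo + int(rng.integers(hi - lo))
    if new >= cur:
        new += 1
    prop = rho.copy()
    if new > cur:
        prop[(rho > cur) & (rho <= new)] -= 1
    else:
        prop[(rho >= new) & (rho < cur)] += 1
    prop[u] = new
    if abs(new - cur) >= 2:
        log_ratio = np.log(_window(cur, L, n)) - np.log(_window(new, L, n))
    else:
        log_ratio = 0.0
    return prop, float(log_ratio)


def _distance_matrix(ranks: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """(N, C) footrule distances between each sample row and each rho_c."""
    return np.abs(ranks[:, None, :] - rho[None, :, :]).sum(axis=2)


def update_assignments(rm: RankMatrix | np.ndarray, state: MixtureState,
                       table: PartitionTable, rng) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs draw of z: P(z_j=c) proportional to
    w_c exp(-alpha_c d(R_j, rho_c)/n) / Z_n(alpha_c).
    Returns (labels, normalized probability matrix)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ranks = rm.ranks if isinstance(rm, RankMatrix) else rm
    n = ranks.shape[1]
    d = _distance_matrix(ranks, state.rho)
    log_z = np.array([log_partition(a, n, table) for a in state.alpha])
    logp = np.log(state.weights)[None, :] - state.alpha[None, :] * d / n - log_z[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(ranks.shape[0])
    z = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return z.astype(np.int64), p


def update_weights(z: np.ndarray, C: int, psi: float, rng) -> np.ndarray:
    """Conjugate draw: weights ~ Dirichlet(psi + n_1, ..., psi + n_C)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = np.bincount(z, minlength=C)
    return rng.dirichlet(psi + counts)


def update_alpha(c: int, rm: RankMatrix | np.ndarray, state: MixtureState,
                 prior: PriorSpec, table: PartitionTable, rng) -> tuple[float, bool]:
    """M-H update of alpha_c: Gaussian random walk on log(alpha) with the
    cluster-c likelihood, exponential prior, and log-transform Jacobian.
    Proposals outside the partition table's grid are rejected."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ranks = rm.ranks if isinstance(rm, RankMatrix) else rm
    n = ranks.shape[1]
    members = ranks[state.z == c]
    n_c = members.shape[0]
    d_c = np.abs(members - state.rho[c]).sum() if n_c else 0.0
    cur = state.alpha[c]
    new = cur * np.exp(prior.alpha_proposal_sd * rng.standard_normal())
    if new > table.alpha_grid[-1] or new < table.alpha_grid[0]:
        return cur, False

    def log_target(a: float) -> float:
        return (-a * d_c / n - n_c * log_partition(a, n, table)
                - prior.alpha_prior_rate * a + np.log(a))

    log_acc = log_target(new) - log_target(cur)
    if np.log(rng.random()) < log_acc:
        return float(new), True
    return float(cur), False


def update_rho(c: int, rm: RankMatrix | np.ndarray, state: MixtureState,
               prior: PriorSpec, rng) -> tuple[np.ndarray, bool]:
    """One leap-and-shift M-H update of rho_c against its members'
    total footrule distance; Z cancels (rho-free for the footrule)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ranks = rm.ranks if isinstance(rm, RankMatrix) else rm
    n = ranks.shape[1]
    members = ranks[state.z == c]
    cur = state.rho[c]
    prop, log_ratio = leap_and_shift_propose(cur, prior.leap(n), rng)
    d_cur = np.abs(members - cur).sum() if members.size else 0.0
    d_new = np.abs(members - prop).sum() if members.size else 0.0
    log_acc = -state.alpha[c] * (d_new - d_cur) / n + log_ratio
    if np.log(rng.random()) < log_acc:
        return prop, True
    return cur, False


# ---------------------------------------------------------------------------
# the full chain

def _log_lik(ranks: np.ndarray, state: MixtureState, table: PartitionTable) -> float:
    """Conditional data log-likelihood given labels:
    sum_j [-alpha_{z_j} d(R_j, rho_{z_j})/n - log Z(alpha_{z_j})]."""
    n = ranks.shape[1]
    d = np.abs(ranks - state.rho[state.z]).sum(axis=1)
    log_z = np.array([log_partition(a, n, table) for a in state.alpha])
    return float(np.sum(-state.alpha[state.z] * d / n - log_z[state.z]))


def run_mcmc(
    rm: RankMatrix | np.ndarray,
    C: int,
    n_iter: int = 2000,
    burn_in: int | None = None,
    thin: int = 1,
    prior: PriorSpec | None = None,
    table: PartitionTable | None = None,
    seed: int = 0,
    init: str = "from-data",
) -> PosteriorSamples:
    """Run the full Metropolis-within-Gibbs chain and store the post-burn-in
    states.  Deterministic under (seed, config).  Empty clusters are safe:
    with no members the alpha and rho updates reduce to their priors."""
    ranks = rm.ranks if isinstance(rm, RankMatrix) else np.asarray(rm)
    N, n = ranks.shape
    if not 1 <= C <= N:
        raise ValueError(f"need 1 <= C <= N; got C={C}, N={N}")
    burn_in = n_iter // 2 if burn_in is None else burn_in
    if not 0 <= burn_in < n_iter:
        raise ValueError("need 0 <= burn_in < n_iter")
    prior = prior or PriorSpec()
    if table is None:
        table = PartitionTable.build(n, seed=seed)
    rng = np.random.default_rng(seed)

    z = rng.integers(C, size=N)
    if init == "from-data":
        # k-means++-style spread: seed each consensus from an observed
        # ranking chosen with probability proportional to its squared
        # footrule distance from the nearest already-chosen one.  Starting
        # two consensus rankings inside the same data mode is the main way
        # short chains get trapped with merged clusters.
        chosen = [int(rng.integers(N))]
        for _ in range(1, C):
            d_near = np.abs(ranks[:, None, :]
                            - ranks[chosen][None, :, :]).sum(axis=2).min(axis=1)
            w = d_near.astype(float) ** 2
            if w.sum() == 0:
                chosen.append(int(rng.integers(N)))
            else:
                chosen.append(int(rng.choice(N, p=w / w.sum())))
        rho = ranks[chosen].copy()
    elif init == "random":
        rho = np.stack([rng.permutation(n) + 1 for _ in range(C)])
    else:
        raise ValueError(f"unknown init: {init!r}")
    state = MixtureState(rho=rho.astype(np.int64), alpha=np.ones(C),
                         z=z, weights=np.full(C, 1.0 / C))

    kept = range(burn_in, n_iter, thin)
    T = len(kept)
    out_rho = np.empty((T, C, n), dtype=np.int64)
    out_alpha = np.empty((T, C))
    out_z = np.empty((T, N), dtype=np.int64)
    out_w = np.empty((T, C))
    out_ll = np.empty(T)
    out_wd = np.empty(T)
    acc = {("alpha", c): [0, 0] for c in range(C)}
    acc.update({("rho", c): [0, 0] for c in range(C)})

    keep_set = set(kept)
    t = 0
    for it in range(n_iter):
        state.z, _ = update_assignments(ranks, state, table, rng)
        state.weights = update_weights(state.z, C, prior.dirichlet_concentration, rng)
        for c in range(C):
            a_new, ok = update_alpha(c, ranks, state, prior, table, rng)
            state.alpha[c] = a_new
            acc[("alpha", c)][0] += ok
            acc[("alpha", c)][1] += 1
            for _ in range(prior.rho_proposals_per_sweep):
                r_new, ok = update_rho(c, ranks, state, prior, rng)
                state.rho[c] = r_new
                acc[("rho", c)][0] += ok
                acc[("rho", c)][1] += 1
        if it in keep_set:
            out_rho[t] = state.rho
            out_alpha[t] = state.alpha
            out_z[t] = state.z
            out_w[t] = state.weights
            out_ll[t] = _log_lik(ranks, state, table)
            out_wd[t] = np.abs(ranks - state.rho[state.z]).sum()
            t += 1

    rates = {k: v[0] / v[1] for k, v in acc.items()}
    config = dict(C=C, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed,
                  init=init, prior=vars(prior).copy(), n=n, N=N,
                  table_method=table.method)
    return PosteriorSamples(rho=out_rho, alpha=out_alpha, z=out_z,
                            weights=out_w, log_lik=out_ll,
                            within_distance=out_wd, acceptance=rates,
                            config=config)


def relabel(samples: PosteriorSamples) -> PosteriorSamples:
    """Undo label switching: greedily match each iteration's clusters to the
    maximum-likelihood iteration by minimal total footrule distance between
    consensus rankings, and apply the matching to rho, alpha, z, weights."""
    if samples.n_stored < 1:
        raise ValueError("no stored iterations")
    C = samples.C
    ref = samples.rho[int(np.argmax(samples.log_lik))]
    rho = samples.rho.copy()
    alpha = samples.alpha.copy()
    z = samples.z.copy()
    w = samples.weights.copy()
    for t in range(samples.n_stored):
        d = np.abs(samples.rho[t][:, None, :] - ref[None, :, :]).sum(axis=2)
        perm = np.full(C, -1)
        dd = d.astype(float).copy()
        for _ in range(C):  # greedy: repeatedly take the cheapest pairing
            i, j = np.unravel_index(np.argmin(dd), dd.shape)
            perm[i] = j
            dd[i, :] = np.inf
            dd[:, j] = np.inf
        rho[t, perm] = samples.rho[t]
        alpha[t, perm] = samples.alpha[t]
        w[t, perm] = samples.weights[t]
        z[t] = perm[samples.z[t]]
    return replace(samples, rho=rho, alpha=alpha, z=z, weights=w)


def diagnostics(samples: PosteriorSamples) -> dict:
    """Summary for convergence inspection: acceptance rates per (move,
    cluster), per-cluster alpha traces, and the within-cluster total
    distance trace."""
    return {
        "acceptance_rates": dict(samples.acceptance),
        "alpha_traces": {c: samples.alpha[:, c].copy() for c in range(samples.C)},
        "within_distance_trace": samples.within_distance.copy(),
        "log_lik_trace": samples.log_lik.copy(),
        "n_stored": samples.n_stored,
    }
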