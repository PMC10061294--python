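"""Shared fixtures: small exact partition tables, a synthetic study cohort
(N=300 samples, n=20 genes, 3 well-separated Mallows components at
alpha=10), and fitted chains over a scan of candidate C values.

The cohort seed is fixed so every test sees the same data; expensive
objects are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from mallowsmix import (PartitionTable, majority_vote, relabel, run_mcmc,
                        sample_mixture, within_cluster_distance_posterior)
from mallowsmix.selection import ClusterFitDraws

STUDY_SEED = 11


@pytest.fixture(scope="session")
def exact_tables() -> dict[int, PartitionTable]:
    return {n: PartitionTable.exact(n) for n in range(2, 8)}


@pytest.fixture(scope="session")
def cohort():
    """(RankMatrix, SyntheticTruth) for the default study conditions."""
    return sample_mixture(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def table20():
    return PartitionTable.build(20, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def c_scan(cohort, table20):
    """Relabeled chains, majority votes and posterior fit draws for C=1..6."""
    rm, _ = cohort
    out = {}
    for C in range(1, 7):
        chain = relabel(run_mcmc(rm, C=C, n_iter=2000, table=table20,
                                 seed=STUDY_SEED + C))
        votes = majority_vote(chain)
        draws = within_cluster_distance_posterior(rm, chain, votes,
                                                  n_draws=1000,
                                                  seed=STUDY_SEED + C)
        out[C] = dict(chain=chain, votes=votes, draws=draws)
    return out


@pytest.fixture(scope="session")
def fit_draws(c_scan) -> ClusterFitDraws:
    return ClusterFitDraws(draws={C: v["draws"] for C, v in c_scan.items()})


@pytest.fixture(scope="session")
def fitted_chain(c_scan):
    """The relabeled chain at the true C=3."""
    return c_scan[3]["chain"]


def spearman(x, y) -> float:
    from scipy.stats import spearmanr
    return float(spearmanr(x, y).statistic)


def brute_force_log_z(n: int, alpha: float) -> float:
    """Independent oracle: direct sum of exp(-alpha*d/n) over all of P_n."""
    from itertools import permutations
    import math
    total = 0.0
    ident = np.arange(1, n + 1)
    for p in permutations(range(1, n + 1)):
        d = int(np.abs(np.array(p) - ident).sum())
        total += math.exp(-alpha * d / n)
    return math.log(total)
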