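"""Fit the Mallows mixture for C=1..6 on the simulated cohort, summarize
the posterior within-cluster sum of distances per C, and pick C at the
elbow.

Expects results/cohort/ from 01_simulate_cohort.py.  Writes the elbow
table, the relative-drop table, the boxplot figure and per-C chains under
results/fits/.
"""

from pathlib import Path

import numpy as np

from mallowsmix import (majority_vote, read_rank_matrix, relabel, run_mcmc,
                        suggest_c, within_cluster_distance_posterior)
from mallowsmix.mallows import PartitionTable
from mallowsmix.plots import plot_elbow
from mallowsmix.selection import ClusterFitDraws, elbow_summary

SEED = 11
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rm = read_rank_matrix(ROOT / "cohort" / "ranks.tsv")
    out = ROOT / "fits"
    out.mkdir(parents=True, exist_ok=True)
    table = PartitionTable.build(rm.n_genes, seed=SEED)

    draws = {}
    for C in range(1, 7):
        chain = relabel(run_mcmc(rm, C=C, n_iter=2200, table=table,
                                 seed=SEED + C))
        votes = majority_vote(chain)
        np.savez(out / f"chain_C{C}.npz", rho=chain.rho, alpha=chain.alpha,
                 z=chain.z, weights=chain.weights, log_lik=chain.log_lik,
                 within_distance=chain.within_distance)
        np.savetxt(out / f"votes_C{C}.tsv", votes, fmt="%d")
        draws[C] = within_cluster_distance_posterior(rm, chain, votes,
                                                     n_draws=1000, seed=SEED)
        rates = {k[0]: round(v, 2) for k, v in chain.acceptance.items()}
        print(f"C={C}: median fit {np.median(draws[C]):.0f}, "
              f"acceptance ~{rates}")

    fits = ClusterFitDraws(draws=draws)
    elbow_summary(fits).to_csv(out / "elbow_summary.tsv", sep="\t",
                               index=False)
    suggestion, drop_table = suggest_c(fits)
    drop_table.to_csv(out / "elbow_drops.tsv", sep="\t", index=False)
    ax = plot_elbow(fits)
    ax.figure.savefig(out / "elbow.png", dpi=120)
    print(f"elbow suggests C = {suggestion} "
          f"(the fit measure plateaus beyond it)")


if __name__ == "__main__":
    main()
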