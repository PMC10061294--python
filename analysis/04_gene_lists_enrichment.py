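"""Characterize the C=3 clusters by their top-ranked genes and test the
planted gene sets for over-representation.

Expects results/fits/ and results/cohort/.  Writes per-cluster gene lists,
co-occurrence counts with KS tests, and enrichment tables under
results/gene_lists/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mallowsmix import (co_occurrence, co_occurrence_ks_test,
                        hypergeom_enrichment, read_gmt, read_rank_matrix,
                        topk_probability)
from mallowsmix.gene_lists import gene_list_table
from mallowsmix.mixture import PosteriorSamples

ROOT = Path(__file__).resolve().parent.parent / "results"
K = 10                 # top-k for an n=20 gene universe
MIN_PROB_EXPLORE = 0.01
MIN_PROB_STRICT = 0.80


def main() -> None:
    rm = read_rank_matrix(ROOT / "cohort" / "ranks.tsv")
    npz = np.load(ROOT / "fits" / "chain_C3.npz")
    chain = PosteriorSamples(rho=npz["rho"], alpha=npz["alpha"], z=npz["z"],
                             weights=npz["weights"], log_lik=npz["log_lik"],
                             within_distance=npz["within_distance"],
                             acceptance={})
    out = ROOT / "gene_lists"
    out.mkdir(parents=True, exist_ok=True)

    glt = gene_list_table(chain, k=K, min_prob=MIN_PROB_EXPLORE,
                          gene_ids=rm.gene_ids)
    for c, df in glt.tables.items():
        df.to_csv(out / f"cluster{c}_k{K}.tsv", sep="\t", index=False)
        print(f"cluster {c}: {len(df)} genes with P(top-{K}) >= "
              f"{MIN_PROB_EXPLORE}; strongest {df.iloc[0]['gene']} "
              f"({df.iloc[0]['probability']:.2f})")

    counts = co_occurrence(glt)
    rows = []
    for c in range(chain.C):
        direction, p = co_occurrence_ks_test(counts, c)
        rows.append(dict(cluster=c, n_top_genes=len(counts.counts[c]),
                         mean_co_occurrence=counts.counts[c].mean(),
                         direction=direction, ks_p=p))
    pd.DataFrame(rows).to_csv(out / "co_occurrence_ks.tsv", sep="\t",
                              index=False)

    collection = read_gmt(ROOT / "cohort" / "gene_sets.gmt")
    for c in range(chain.C):
        probs = topk_probability(chain, c, K)
        strict = [g for g, p in zip(rm.gene_ids, probs)
                  if p >= MIN_PROB_STRICT]
        res = hypergeom_enrichment(strict, collection, rm.gene_ids)
        res.to_csv(out / f"enrichment_cluster{c}.tsv", sep="\t", index=False)
        sig = res[res["significant"]]["set_name"].tolist()
        print(f"cluster {c}: strict list of {len(strict)} genes; "
              f"significant sets {sig}")


if __name__ == "__main__":
    main()
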