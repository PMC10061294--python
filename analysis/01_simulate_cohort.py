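"""Simulate the study cohort: N=300 samples of full rankings of n=20 genes
from a 3-component Mallows mixture (alpha=10, equal weights, high
separation), render it as an expression-like table, and plant gene-set
fixtures with known enrichment.

Writes ranks, expression, true labels/consensus rankings and the GMT
fixture under results/cohort/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mallowsmix import (ranks_to_expression, sample_mixture, write_gmt,
                        write_rank_matrix)
from mallowsmix.synthetic import make_gene_set_fixtures

SEED = 11
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rm, truth = sample_mixture(seed=SEED)
    write_rank_matrix(rm, OUT / "ranks.tsv")

    expr = ranks_to_expression(rm, noise_scale=0.5, seed=SEED)
    pd.DataFrame(expr.values, index=expr.gene_ids,
                 columns=expr.sample_ids).to_csv(OUT / "expression.tsv",
                                                 sep="\t",
                                                 index_label="gene_id")
    pd.DataFrame({"sample_id": rm.sample_ids,
                  "label": truth.labels}).to_csv(OUT / "true_labels.tsv",
                                                 sep="\t", index=False)
    np.savetxt(OUT / "true_consensus.tsv", truth.rho, fmt="%d",
               delimiter="\t")
    write_gmt(make_gene_set_fixtures(truth, rm.gene_ids, seed=SEED),
              OUT / "gene_sets.gmt")

    counts = np.bincount(truth.labels, minlength=truth.C)
    print(f"cohort: {rm.n_samples} samples x {rm.n_genes} genes, "
          f"{truth.C} components (sizes {counts.tolist()}), "
          f"min pairwise consensus footrule {truth.separation} "
          f"(max possible {rm.n_genes ** 2 // 2})")
    print(f"wrote ranks, expression, truth and gene-set fixtures to {OUT}")


if __name__ == "__main__":
    main()
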