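"""Co-localization stability of the clustering across C, and agreement of
the C=3 majority-vote partition with the known truth.

Expects results/fits/ from 02_fit_and_select_c.py.  Writes the S matrix
and its heatmap under results/stability/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mallowsmix import colocalization_matrix, read_rank_matrix
from mallowsmix.plots import plot_colocalization
from mallowsmix.stability import StabilityAssignments

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rm = read_rank_matrix(ROOT / "cohort" / "ranks.tsv")
    truth = pd.read_csv(ROOT / "cohort" / "true_labels.tsv", sep="\t")
    out = ROOT / "stability"
    out.mkdir(parents=True, exist_ok=True)

    votes = {C: np.loadtxt(ROOT / "fits" / f"votes_C{C}.tsv", dtype=int)
             for C in range(2, 7)}
    S = colocalization_matrix(StabilityAssignments(labels=votes))
    pd.DataFrame(S.S, index=rm.sample_ids, columns=rm.sample_ids).to_csv(
        out / "colocalization.tsv", sep="\t", index_label="sample_id")
    ax = plot_colocalization(S, external_labels=truth["label"].to_numpy())
    ax.figure.savefig(out / "colocalization.png", dpi=120)

    same = truth["label"].to_numpy()[:, None] == truth["label"].to_numpy()[None, :]
    off = ~np.eye(len(truth), dtype=bool)
    within = S.S[same & off].mean()
    between = S.S[~same].mean()
    print(f"S over C={S.c_min}..{S.c_max}: mean co-clustering "
          f"{within:.3f} within true clusters vs {between:.3f} between "
          f"(gap {within - between:.3f})")

    from sklearn.metrics import adjusted_rand_score
    votes3 = np.loadtxt(ROOT / "fits" / "votes_C3.tsv", dtype=int)
    ari = adjusted_rand_score(truth["label"], votes3)
    print(f"C=3 majority vote vs truth: adjusted Rand index {ari:.3f}")


if __name__ == "__main__":
    main()
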