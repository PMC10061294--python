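"""Chi-square comparisons of rank-based clusters against published subtype
classifications, recomputed from the bundled printed contingency tables,
plus the fitted clustering versus the simulated truth.

Writes the test results under results/comparisons/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mallowsmix import compare_labelings, contingency_test
from mallowsmix.datasets import (brca_vs_pam50, kirc_vs_mrna_subtypes,
                                 squamous_vs_integrative_clusters)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "comparisons"
    out.mkdir(parents=True, exist_ok=True)
    rows = []

    res = contingency_test(squamous_vs_integrative_clusters(), min_expected=5)
    rows.append(dict(comparison="squamous_vs_integrative", chi2=res.chi2,
                     df=res.df, p=res.p_value,
                     note=f"sparse columns dropped: {res.dropped_categories}"))
    res.formatted().to_csv(out / "squamous_vs_integrative.tsv", sep="\t")

    res = contingency_test(kirc_vs_mrna_subtypes())
    rows.append(dict(comparison="kirc_vs_mrna", chi2=res.chi2, df=res.df,
                     p=res.p_value, note=""))
    res.formatted().to_csv(out / "kirc_vs_mrna.tsv", sep="\t")

    res = contingency_test(brca_vs_pam50())
    rows.append(dict(comparison="brca_vs_pam50", chi2=res.chi2, df=res.df,
                     p=res.p_value, note=""))
    res.formatted().to_csv(out / "brca_vs_pam50.tsv", sep="\t")

    votes_path = ROOT / "fits" / "votes_C3.tsv"
    if votes_path.exists():
        truth = pd.read_csv(ROOT / "cohort" / "true_labels.tsv", sep="\t")
        ours = pd.Series(np.loadtxt(votes_path, dtype=int).astype(str),
                         index=truth["sample_id"])
        theirs = pd.Series(truth["label"].astype(str).to_numpy(),
                           index=truth["sample_id"])
        res = compare_labelings(ours, theirs)
        rows.append(dict(comparison="fitted_C3_vs_simulated_truth",
                         chi2=res.chi2, df=res.df, p=res.p_value, note=""))
        res.formatted().to_csv(out / "fitted_vs_truth.tsv", sep="\t")

    table = pd.DataFrame(rows)
    table.to_csv(out / "chi_square_tests.tsv", sep="\t", index=False)
    for _, r in table.iterrows():
        print(f"{r['comparison']}: chi2 = {r['chi2']:.2f}, df = {r['df']}, "
              f"p = {r['p']:.3g} {r['note']}")


if __name__ == "__main__":
    main()
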