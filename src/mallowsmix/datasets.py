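"""Published cross-tabulations bundled for the labeling-comparison analyses.

These are the printed contingency tables from a pan-cancer TCGA study that
clustered 2617 tumor samples by their within-sample gene rankings
(RankClusters), compared against previously published subtype
classifications: integrative multi-omics clusters and mRNA clusters for
squamous cell carcinomas, mRNA subtypes for renal clear cell carcinoma
(KIRC), and PAM50 subtypes for breast cancer (BRCA).  They let the
contingency machinery be exercised and checked against the published
statistics without any external download.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "squamous_vs_integrative_clusters",
    "kirc_vs_mrna_subtypes",
    "brca_vs_pam50",
]


def squamous_vs_integrative_clusters() -> pd.DataFrame:
    """Pan-squamous RankClusters (3, 5, 6) versus integrative multi-omics
    clusters (3x8 counts).  Most squamous samples concentrate in iC10,
    iC20, iC25 and iC27; the remaining columns are sparse."""
    return pd.DataFrame(
        [[1, 0, 26, 0, 0, 26, 14, 19],
         [2, 11, 93, 3, 6, 8, 24, 36],
         [0, 3, 49, 0, 0, 0, 34, 74]],
        index=["RankCluster 3", "RankCluster 5", "RankCluster 6"],
        columns=["iC2", "iC7", "iC10", "iC13", "iC17", "iC20", "iC25", "iC27"],
    )


def kirc_vs_mrna_subtypes() -> pd.DataFrame:
    """KIRC RankClusters (2, 15) versus the four published mRNA subtypes
    of renal clear cell carcinoma (2x4 counts)."""
    return pd.DataFrame(
        [[3, 63, 32, 64],
         [130, 24, 51, 20]],
        index=["RankCluster 2", "RankCluster 15"],
        columns=["mRNA1", "mRNA2", "mRNA3", "mRNA4"],
    )


def brca_vs_pam50() -> pd.DataFrame:
    """BRCA RankClusters (7, 8, 11) versus PAM50 breast cancer subtypes
    (3x5 counts)."""
    return pd.DataFrame(
        [[0, 0, 10, 83, 10],
         [161, 9, 2, 0, 28],
         [91, 91, 33, 0, 21]],
        index=["RankCluster 7", "RankCluster 8", "RankCluster 11"],
        columns=["Luminal A", "Luminal B", "Her2-enriched",
                 "Basal-like", "Normal-like"],
    )
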