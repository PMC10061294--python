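"""Figure rendering: elbow boxplots, co-localization heatmap, top-gene
probability profiles, enrichment bars.  All functions take an optional
Axes and return it, so they compose into larger figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402  (headless rendering)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .selection import ClusterFitDraws
from .stability import ColocalizationMatrix, order_for_display

__all__ = ["plot_elbow", "plot_colocalization", "plot_topk_profiles",
           "plot_enrichment"]


def plot_elbow(fits: ClusterFitDraws, ax=None):
    """Boxplots of the posterior within-cluster sum of distances per C."""
    ax = ax or plt.figure(figsize=(8, 4)).add_subplot()
    cs = fits.candidates
    ax.boxplot([fits.draws[C] for C in cs], tick_labels=[str(C) for C in cs],
               whis=1.5, flierprops=dict(markersize=2))
    ax.set_xlabel("number of clusters C")
    ax.set_ylabel("within-cluster sum of footrule distances")
    return ax


def plot_colocalization(S: ColocalizationMatrix, external_labels=None, ax=None):
    """Heatmap of the co-localization matrix, samples ordered for display."""
    ax = ax or plt.figure(figsize=(6, 5)).add_subplot()
    order = order_for_display(S, external_labels)
    im = ax.imshow(S.S[np.ix_(order, order)], vmin=0, vmax=1, cmap="Blues",
                   interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="co-clustering fraction")
    ax.set_title(f"pairwise co-localization, C = {S.c_min}..{S.c_max}")
    return ax


def plot_topk_profiles(prob_by_cluster: dict[int, np.ndarray], k: int,
                       min_prob: float = 0.01, ax=None):
    """Per-cluster profile of sorted top-k probabilities (above min_prob)."""
    ax = ax or plt.figure(figsize=(8, 4)).add_subplot()
    offset = 0
    for c in sorted(prob_by_cluster):
        p = np.sort(prob_by_cluster[c])[::-1]
        p = p[p >= min_prob]
        ax.plot(np.arange(offset, offset + p.size), p, label=f"cluster {c}")
        offset += p.size
    ax.set_xlabel(f"genes by decreasing P(top-{k}), per cluster")
    ax.set_ylabel(f"P(consensus rank ≤ {k})")
    ax.legend(fontsize=7, ncol=4)
    return ax


def plot_enrichment(rows: pd.DataFrame, max_sets: int = 15, ax=None):
    """Horizontal bars of -log10 adjusted p, fold enrichment annotated."""
    ax = ax or plt.figure(figsize=(7, 4)).add_subplot()
    top = rows.nsmallest(max_sets, "adjusted_p")[::-1]
    y = np.arange(len(top))
    ax.barh(y, -np.log10(np.maximum(top["adjusted_p"], 1e-300)))
    for yi, (_, row) in zip(y, top.iterrows()):
        ax.text(0.05, yi, f"FE={row['fold_enrichment']:.1f}", va="center",
                fontsize=7)
    ax.set_yticks(y, top["set_name"], fontsize=7)
    ax.set_xlabel("-log10 adjusted p")
    return ax
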