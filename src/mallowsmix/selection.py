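"""Choosing the number of clusters C from the posterior cluster-fit measure.

The fit measure for a given C is the within-cluster sum of footrule
distances of the observed rankings from their cluster's consensus ranking,
with each sample held at its majority-vote cluster.  Posterior realizations
of the measure (default 1000 per C) are summarized as boxplots over C; the
chosen C sits at the "elbow" where the marked decrease turns into a
plateau.  ``suggest_c`` encodes a simple relative-drop rule, but the final
choice is left to visual inspection — the rule is advisory only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_ranks import RankMatrix
from .mixture import PosteriorSamples

__all__ = [
    "ClusterFitDraws",
    "within_cluster_distance_posterior",
    "elbow_summary",
    "suggest_c",
]


@dataclass
class ClusterFitDraws:
    """Posterior realizations of the within-cluster sum of distances,
    one vector per candidate C."""

    draws: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for C, v in self.draws.items():
            v = np.asarray(v)
            if np.any(v < 0):
                raise ValueError(f"negative fit realizations for C={C}")
            self.draws[C] = v

    @property
    def candidates(self) -> list[int]:
        return sorted(self.draws)


def within_cluster_distance_posterior(
    rm: RankMatrix | np.ndarray,
    samples: PosteriorSamples,
    assignments: np.ndarray,
    n_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Posterior realizations of sum_j d(R_j, rho_{zbar_j}).

    ``assignments`` are the fixed majority-vote labels from the same
    relabeled chain; posterior states are subsampled uniformly without
    replacement.  Requesting more draws than stored iterations is an error.
    """
    ranks = rm.ranks if isinstance(rm, RankMatrix) else np.asarray(rm)
    assignments = np.asarray(assignments)
    if n_draws > samples.n_stored:
        raise ValueError(
            f"requested {n_draws} draws but only {samples.n_stored} stored iterations"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(samples.n_stored, size=n_draws, replace=False)
    out = np.empty(n_draws)
    for k, t in enumerate(idx):
        out[k] = np.abs(ranks - samples.rho[t][assignments]).sum()
    return out


def elbow_summary(fits: ClusterFitDraws) -> pd.DataFrame:
    """Boxplot summary per candidate C: median, Q1/Q3 (linear-interpolation
    quantiles), and Tukey whisker bounds (the most extreme realizations
    within 1.5*IQR of the box)."""
    if len(fits.draws) < 2:
        raise ValueError("need at least 2 candidate C values")
    rows = []
    for C in fits.candidates:
        v = np.asarray(fits.draws[C], dtype=float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
        iqr = q3 - q1
        lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_lim) & (v <= hi_lim)]
        rows.append(dict(C=C, median=med, q1=q1, q3=q3,
                         whisker_low=inside.min(), whisker_high=inside.max(),
                         n_outliers=int(((v < lo_lim) | (v > hi_lim)).sum())))
    return pd.DataFrame(rows)


def suggest_c(fits: ClusterFitDraws, drop_threshold: float = 0.02) -> tuple[int, pd.DataFrame]:
    """Advisory elbow rule: the largest C whose relative drop in posterior
    median versus C-1 exceeds ``drop_threshold``; with no qualifying drop,
    the smallest candidate.  Candidate C values must be contiguous.
    Returns (suggested C, table of per-step relative drops)."""
    cs = fits.candidates
    if cs != list(range(cs[0], cs[-1] + 1)):
        raise ValueError("candidate C values must be contiguous")
    med = {C: float(np.median(fits.draws[C])) for C in cs}
    rows = []
    suggestion = cs[0]
    for prev, C in zip(cs, cs[1:]):
        drop = (med[prev] - med[C]) / med[prev] if med[prev] > 0 else 0.0
        rows.append(dict(C=C, median=med[C], relative_drop=drop))
        if drop > drop_threshold:
            suggestion = C
    return suggestion, pd.DataFrame(rows)
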