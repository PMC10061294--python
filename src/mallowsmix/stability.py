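"""Clustering stability across the number of clusters C.

Mixture-based clustering is nonhierarchical: partitions at different C are
fitted independently.  If pairs of samples nevertheless stay together as C
varies, the grouping reflects structure in the data rather than the model
choice.  The co-localization matrix S records, for every pair of samples,
the fraction of C values (over a contiguous range [C_m, C_M], default
10..30) at which the two samples share a majority-vote cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import mode

from .mixture import PosteriorSamples

__all__ = [
    "StabilityAssignments",
    "ColocalizationMatrix",
    "majority_vote",
    "colocalization_matrix",
    "order_for_display",
]

DEFAULT_C_RANGE = (10, 30)


@dataclass
class StabilityAssignments:
    """Majority-vote label vectors keyed by C, over a contiguous range."""

    labels: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        sizes = {len(v) for v in self.labels.values()}
        if len(sizes) > 1:
            raise ValueError("label vectors have differing lengths")
        for C, v in self.labels.items():
            v = np.asarray(v)
            if v.size and (v.min() < 0 or v.max() >= C):
                raise ValueError(f"labels out of range for C={C}")
            self.labels[C] = v

    @property
    def c_range(self) -> tuple[int, int]:
        cs = sorted(self.labels)
        return cs[0], cs[-1]


@dataclass
class ColocalizationMatrix:
    S: np.ndarray
    c_min: int
    c_max: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if not np.allclose(S, S.T):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(S), 1.0):
            raise ValueError("S must have unit diagonal")
        if S.min() < 0 or S.max() > 1 + 1e-12:
            raise ValueError("S entries must lie in [0, 1]")
        self.S = S


def majority_vote(samples: PosteriorSamples) -> np.ndarray:
    """Modal sampled label per sample over the stored (relabeled) iterations;
    exact ties go to the smallest cluster index."""
    # scipy's mode already breaks ties by the smallest value
    return mode(samples.z, axis=0).mode.astype(np.int64)


def colocalization_matrix(assign: StabilityAssignments) -> ColocalizationMatrix:
    """S_ij = fraction of C in [C_m, C_M] at which samples i and j share a
    majority-vote cluster.  Every C in the contiguous range must be present."""
    c_min, c_max = assign.c_range
    missing = [C for C in range(c_min, c_max + 1) if C not in assign.labels]
    if missing:
        raise ValueError(f"missing C values in range: {missing}")
    n_c = c_max - c_min + 1
    mats = [
        (assign.labels[C][:, None] == assign.labels[C][None, :])
        for C in range(c_min, c_max + 1)
    ]
    S = np.mean(mats, axis=0)
    return ColocalizationMatrix(S=S, c_min=c_min, c_max=c_max)


def order_for_display(S: ColocalizationMatrix | np.ndarray,
                      external_labels=None) -> np.ndarray:
    """Sample ordering for heatmap rendering: by external label when given
    (stable within label), otherwise by average-linkage clustering of 1-S."""
    M = S.S if isinstance(S, ColocalizationMatrix) else np.asarray(S)
    N = M.shape[0]
    if external_labels is not None:
        external_labels = np.asarray(external_labels)
        if external_labels.shape[0] != N:
            raise ValueError("external label length mismatch")
        return np.argsort(external_labels, kind="stable")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    # guard tiny negative entries from float fuzz before condensing
    Z = average(squareform(np.maximum(D, 0.0), checks=False))
    return np.asarray(leaves_list(Z), dtype=np.int64)
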