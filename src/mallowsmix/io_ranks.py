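"""Reading expression tables and converting them to within-sample gene rankings.

The clustering model consumes *full rankings*: for every sample, the genes
are ordered from the most highly expressed (rank 1) down to the least
expressed (rank n).  Only the within-sample order matters, which makes the
downstream analysis invariant to any strictly monotone, sample-specific
rescaling of the expression values — the property that lets heterogeneous
cohorts (different tissues, batches, platforms) be analyzed jointly.

This module deliberately refuses unimputed input: the Mallows likelihood is
defined on complete permutations, so missing entries must be handled (by
imputation or gene filtering) before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RankMatrix",
    "read_expression_table",
    "to_rank_matrix",
    "write_rank_matrix",
    "read_rank_matrix",
    "read_labels",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with an explicit missing-data mask.

    ``values`` has shape (n_genes, n_samples); entries where
    ``missing_mask`` is True are undefined (stored as NaN).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise ValueError("id lists do not match matrix dimensions")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        bad = ~np.isfinite(self.values) & ~self.missing_mask
        if bad.any():
            raise ValueError(
                "non-finite expression values present that are not flagged missing"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.allclose(
                np.where(self.missing_mask, 0.0, self.values),
                np.where(other.missing_mask, 0.0, other.values),
            )
        )


@dataclass
class RankMatrix:
    """N samples × n genes; each row is a full permutation of 1..n.

    Rank 1 marks the most highly expressed gene in that sample.
    """

    ranks: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        n_samples, n_genes = self.ranks.shape
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise ValueError("id lists do not match matrix dimensions")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        expected = np.arange(1, n_genes + 1)
        for i, row in enumerate(self.ranks):
            if not np.array_equal(np.sort(row), expected):
                raise ValueError(
                    f"row for sample {self.sample_ids[i]!r} is not a "
                    f"permutation of 1..{n_genes}"
                )

    @property
    def n_samples(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.ranks, other.ranks)
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


def read_expression_table(
    path,
    orientation: str = "genes-in-rows",
    delimiter: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression table with id header row and id first column.

    ``orientation`` declares whether rows are genes or samples; there is no
    auto-detection (silent transposition is a classic failure mode).  Empty
    cells become flagged missing values.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed table {path}: {exc}") from exc
    non_numeric = df.columns[
        [not np.issubdtype(d, np.number) for d in df.dtypes]
    ]
    if len(non_numeric):
        raise ValueError(
            f"non-numeric column(s) in {path}: {list(non_numeric)[:5]}"
        )
    if orientation == "samples-in-rows":
        df = df.T
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def to_rank_matrix(
    expr: ExpressionMatrix,
    tie_policy: str = "random",
    seed: int | None = None,
) -> RankMatrix:
    """Convert expression values to per-sample full rankings (descending).

    The largest value in a sample gets rank 1.  Ties are broken per
    ``tie_policy``: "random" (requires a seed; reproducible) or "stable"
    (first-occurrence order among tied genes).
    """
    if expr.missing_mask.any():
        n_miss = int(expr.missing_mask.sum())
        raise ValueError(
            f"{n_miss} missing entries present; impute or drop genes before ranking"
        )
    if tie_policy not in ("random", "stable"):
        raise ValueError(f"unknown tie_policy: {tie_policy!r}")
    if tie_policy == "random" and seed is None:
        raise ValueError("tie_policy='random' requires a seed for reproducibility")
    rng = np.random.default_rng(seed)
    n_genes, n_samples = expr.values.shape
    ranks = np.empty((n_samples, n_genes), dtype=np.int64)
    for j in range(n_samples):
        col = expr.values[:, j]
        if tie_policy == "random":
            tiebreak = rng.random(n_genes)
        else:
            tiebreak = -np.arange(n_genes, dtype=float)  # first occurrence wins
        # lexsort: primary key descending value, secondary key per policy
        order = np.lexsort((-tiebreak, -col))
        ranks[j, order] = np.arange(1, n_genes + 1)
    return RankMatrix(ranks=ranks, gene_ids=list(expr.gene_ids),
                      sample_ids=list(expr.sample_ids))


def write_rank_matrix(rm: RankMatrix, path) -> None:
    """Write a rank matrix as TSV (samples in rows, genes in columns)."""
    df = pd.DataFrame(rm.ranks, index=rm.sample_ids, columns=rm.gene_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_rank_matrix(path) -> RankMatrix:
    """Read a rank matrix written by :func:`write_rank_matrix`.

    Every row must be a full permutation of 1..n; a violating row is
    reported by sample id.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    ranks = df.to_numpy()
    if not np.issubdtype(ranks.dtype, np.integer):
        if np.isnan(ranks.astype(float)).any():
            raise ValueError(f"missing ranks in {path}")
        as_int = ranks.astype(np.int64)
        if not np.allclose(ranks.astype(float), as_int):
            raise ValueError(f"non-integer ranks in {path}")
        ranks = as_int
    return RankMatrix(  # permutation invariant checked in __post_init__
        ranks=ranks,
        gene_ids=[str(g) for g in df.columns],
        sample_ids=[str(s) for s in df.index],
    )


def read_labels(path) -> pd.Series:
    """Read a two-column TSV (sample_id, label) into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"label file {path} must have exactly two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in label file: {dup!r}")
    return s
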