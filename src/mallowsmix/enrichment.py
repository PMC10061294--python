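"""Over-representation statistics for cluster gene lists, and chi-square
comparison of clusterings against external sample labelings.

Enrichment uses the one-sided (upper-tail) hypergeometric test with an
explicit background universe — here the analyzed gene set itself, so that
a curated pre-selection of genes cannot masquerade as biology.  Every gene
set is intersected with the background before testing, the gene list must
be contained in the background (the classic background bug is an error,
not a warning), p-values are Benjamini-Hochberg corrected across all
tested sets, and fold enrichment is the ratio of the set's frequency in
the list to its frequency in the background.

Label comparisons cross-tabulate two labelings of the same samples and
apply Pearson's chi-square test without continuity correction, reporting
percentages of the grand total alongside the counts.  Sparse categories
(any expected count below ``min_expected``) can be dropped before testing,
which published analyses of such tables commonly do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "LabelComparison",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrichment",
    "bh_adjust",
    "contingency_test",
    "compare_labelings",
]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics) with a provenance note."""

    sets: dict[str, set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class LabelComparison:
    """Cross-tabulation of two labelings with the chi-square test result."""

    table: pd.DataFrame          # counts
    percentages: pd.DataFrame    # of grand total, one decimal
    chi2: float
    df: int
    p_value: float
    n_dropped: int = 0           # samples missing a label on either side
    dropped_categories: list = field(default_factory=list)

    def formatted(self) -> pd.DataFrame:
        """'count (pct)' presentation matching the published table style."""
        out = self.table.astype(str).copy()
        for r in self.table.index:
            for c in self.table.columns:
                pct = self.percentages.loc[r, c]
                pct_s = "0" if pct == 0 else f"{pct:.1f}"
                out.loc[r, c] = f"{self.table.loc[r, c]} ({pct_s})"
        return out


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-delimited GMT file (name, description, members...).

    Duplicate members within a set are dropped; a line without members is a
    parse error reported with its line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = set(members)
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.provenance or name,
                                *sorted(members)]) + "\n")


def hypergeom_enrichment(
    gene_list,
    collection: GeneSetCollection,
    background,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set in the list.

    Returns one row per set: overlap, list size, effective set size
    (set ∩ background), background size, p (= P(X >= overlap)), BH-adjusted
    p across all tested sets, fold enrichment, and a significance flag at
    adjusted p < 0.05.  Rows are sorted by adjusted p then name.
    """
    gene_list = set(gene_list)
    background = set(background)
    stray = gene_list - background
    if stray:
        raise ValueError(
            f"{len(stray)} gene(s) in the list are not in the background "
            f"(e.g. {sorted(stray)[:3]}); fix the background universe"
        )
    M, N = len(background), len(gene_list)
    rows = []
    for name, members in collection.sets.items():
        eff = members & background
        K = len(eff)
        x = len(gene_list & eff)
        p = float(hypergeom.sf(x - 1, M, K, N)) if K else 1.0
        fe = (x / N) / (K / M) if K and N else 0.0
        rows.append(dict(set_name=name, overlap=x, list_size=N,
                         effective_set_size=K, background_size=M,
                         p_value=min(p, 1.0), fold_enrichment=fe))
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
    df["significant"] = df["adjusted_p"] < 0.05
    return df.sort_values(["adjusted_p", "set_name"]).reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contingency_test(table: pd.DataFrame,
                     min_expected: float | None = None) -> LabelComparison:
    """Pearson chi-square test (no continuity correction) on a contingency
    table of counts; percentages are of the grand total of the *input*
    table, to one decimal.

    With ``min_expected`` set, columns (then rows) containing an expected
    count below the threshold are dropped before the test — the counts and
    percentage panels still show the full table.
    """
    table = pd.DataFrame(table)
    counts = table.to_numpy()
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("contingency table must hold non-negative integer counts")
    test_table = table
    dropped: list = []
    if min_expected is not None:
        expected = _expected(test_table.to_numpy())
        keep_cols = (expected >= min_expected).all(axis=0)
        dropped += [c for c, k in zip(test_table.columns, keep_cols) if not k]
        test_table = test_table.loc[:, keep_cols]
        expected = _expected(test_table.to_numpy())
        keep_rows = (expected >= min_expected).all(axis=1)
        dropped += [r for r, k in zip(test_table.index, keep_rows) if not k]
        test_table = test_table.loc[keep_rows, :]
    if test_table.shape[0] < 2 or test_table.shape[1] < 2:
        raise ValueError("need at least 2 categories on each axis for chi-square")
    chi2, p, df, _ = chi2_contingency(test_table.to_numpy(), correction=False)
    pct = (table / table.to_numpy().sum() * 100).round(1)
    return LabelComparison(table=table, percentages=pct, chi2=float(chi2),
                           df=int(df), p_value=float(p),
                           dropped_categories=dropped)


def compare_labelings(labels_a: pd.Series, labels_b: pd.Series,
                      min_expected: float | None = None) -> LabelComparison:
    """Cross-tabulate two sample labelings (shared ids only; samples
    missing a label in either are dropped and counted) and chi-square test
    the association."""
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    shared = labels_a.index.intersection(labels_b.index)
    a, b = labels_a.loc[shared], labels_b.loc[shared]
    ok = a.notna() & b.notna()
    n_dropped = (len(labels_a) - ok.sum()) + (len(labels_b) - ok.sum()) \
        - (len(labels_a) - len(shared)) - (len(labels_b) - len(shared))
    tab = pd.crosstab(a[ok], b[ok])
    res = contingency_test(tab, min_expected=min_expected)
    res.n_dropped = int((~ok).sum())
    return res


def _expected(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    return np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
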