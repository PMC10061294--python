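"""End-to-end orchestration: rank -> fit over a C range -> elbow ->
stability -> gene lists -> enrichment -> labeling comparisons.

Every stochastic stage derives its generator from the single configured
seed plus a fixed stage tag, so a rerun with the same config reproduces
every output byte for byte.  Per-C fits are fully independent runs (no
warm-starting across C): the mixture method is nonhierarchical, and the
stability analysis depends on that independence being real.

Stage failures abort with the stage name; partial outputs are kept next
to a FAILED marker naming the stage and cause.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import hypergeom_enrichment, read_gmt
from .gene_lists import DEFAULT_K_GRID, gene_list_table, topk_probability
from .io_ranks import (RankMatrix, read_expression_table, read_labels,
                       read_rank_matrix, to_rank_matrix, write_rank_matrix)
from .mallows import PartitionTable
from .mixture import PosteriorSamples, PriorSpec, relabel, run_mcmc
from .plots import (plot_colocalization, plot_elbow, plot_enrichment,
                    plot_topk_profiles)
from .selection import (ClusterFitDraws, elbow_summary, suggest_c,
                        within_cluster_distance_posterior)
from .stability import (StabilityAssignments, colocalization_matrix,
                        majority_vote)

__all__ = ["PipelineConfig", "run_pipeline", "subset_genes"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    # input: exactly one of expression_path / ranks_path
    expression_path: str | None = None
    ranks_path: str | None = None
    orientation: str = "genes-in-rows"
    delimiter: str = "\t"
    gene_subset: str | None = None     # path, or "random:<m>:<seed>"
    # candidate cluster numbers
    elbow_c_range: tuple[int, int] = (2, 30)
    stability_c_range: tuple[int, int] = (10, 30)
    final_c: int | None = None         # None -> use suggest_c's advice
    # MCMC settings
    n_iter: int = 2000
    burn_in: int | None = None
    thin: int = 1
    prior: PriorSpec = field(default_factory=PriorSpec)
    # summaries
    n_fit_draws: int = 1000
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    exploration_min_prob: float = 0.01
    enrichment_min_prob: float = 0.80
    enrichment_k: int = 100
    gmt_path: str | None = None
    label_paths: dict[str, str] = field(default_factory=dict)
    # bookkeeping
    seed: int = 0
    out_dir: str = "pipeline_out"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.prior, dict):
            self.prior = PriorSpec(**self.prior)
        for name in ("elbow_c_range", "stability_c_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
            setattr(self, name, (int(lo), int(hi)))
        self.k_grid = tuple(int(k) for k in self.k_grid)
        if (self.expression_path is None) == (self.ranks_path is None):
            raise ValueError("provide exactly one of expression_path / ranks_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _stage_rng_seed(config_seed: int, tag: str, extra: int = 0) -> int:
    """Stable per-stage integer seed below 2**31."""
    import zlib
    ss = np.random.SeedSequence([config_seed, zlib.crc32(tag.encode()), extra])
    return int(ss.generate_state(1)[0] % (2**31))


def subset_genes(rm_or_expr, subset, seed_hint: int = 0):
    """Restrict to a gene subset: a list of gene ids, a one-per-line file
    path, or "random:<m>:<seed>".  Ranks are recomputed from the retained
    columns' relative order (subsetting rank values directly would break
    the permutation invariant)."""
    gene_ids = rm_or_expr.gene_ids
    if isinstance(subset, str) and subset.startswith("random:"):
        _, m, s = subset.split(":")
        rng = np.random.default_rng(int(s))
        chosen = sorted(rng.choice(len(gene_ids), size=int(m), replace=False))
        keep = [gene_ids[i] for i in chosen]
    elif isinstance(subset, str):
        keep = [ln.strip() for ln in open(subset) if ln.strip()]
    else:
        keep = list(subset)
    unknown = set(keep) - set(gene_ids)
    if unknown:
        raise ValueError(f"unknown gene id(s): {sorted(unknown)[:5]}")
    idx = [gene_ids.index(g) for g in keep]
    if isinstance(rm_or_expr, RankMatrix):
        sub = rm_or_expr.ranks[:, idx]
        new_ranks = np.empty_like(sub)
        for j in range(sub.shape[0]):  # re-rank retained columns
            order = np.argsort(sub[j])
            new_ranks[j, order] = np.arange(1, len(idx) + 1)
        return RankMatrix(ranks=new_ranks, gene_ids=keep,
                          sample_ids=list(rm_or_expr.sample_ids))
    from .io_ranks import ExpressionMatrix
    return ExpressionMatrix(values=rm_or_expr.values[idx],
                            gene_ids=keep,
                            sample_ids=list(rm_or_expr.sample_ids),
                            missing_mask=rm_or_expr.missing_mask[idx])


def _fit_one(rm: RankMatrix, C: int, cfg: PipelineConfig,
             table: PartitionTable) -> PosteriorSamples:
    samples = run_mcmc(rm, C=C, n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                       thin=cfg.thin, prior=cfg.prior, table=table,
                       seed=_stage_rng_seed(cfg.seed, "fit", C))
    return relabel(samples)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole analysis; returns the output directory.

    Artifacts: per-C majority-vote assignments, the elbow table (and the
    suggestion of C), the co-localization matrix, per-cluster gene lists
    on the k grid, enrichment tables when a GMT is given, contingency
    comparisons when label files are given, and a manifest echoing config,
    seeds and versions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "outputs": [], "stages": []}
    config.to_yaml(out / "config.yaml")
    manifest["outputs"].append("config.yaml")
    stage = "setup"
    try:
        # ---- input ------------------------------------------------------
        stage = "input"
        if config.expression_path:
            expr = read_expression_table(config.expression_path,
                                         config.orientation, config.delimiter)
            if config.gene_subset:
                expr = subset_genes(expr, config.gene_subset)
            rm = to_rank_matrix(expr, tie_policy="random",
                                seed=_stage_rng_seed(config.seed, "rank"))
        else:
            rm = read_rank_matrix(config.ranks_path)
            if config.gene_subset:
                rm = subset_genes(rm, config.gene_subset)
        write_rank_matrix(rm, out / "ranks.tsv")
        manifest["outputs"].append("ranks.tsv")
        n = rm.n_genes

        # ---- fits over the union of C ranges ----------------------------
        stage = "fit"
        table = PartitionTable.build(n, seed=_stage_rng_seed(config.seed, "partition"))
        e_lo, e_hi = config.elbow_c_range
        s_lo, s_hi = config.stability_c_range
        all_c = sorted(set(range(e_lo, e_hi + 1)) | set(range(s_lo, s_hi + 1)))
        fits: dict[int, PosteriorSamples] = {}
        votes: dict[int, np.ndarray] = {}
        for C in all_c:
            fits[C] = _fit_one(rm, C, config, table)
            votes[C] = majority_vote(fits[C])
        votes_df = pd.DataFrame({f"C={C}": votes[C] for C in all_c},
                                index=rm.sample_ids)
        votes_df.to_csv(out / "majority_vote_assignments.tsv", sep="\t",
                        index_label="sample_id")
        manifest["outputs"].append("majority_vote_assignments.tsv")

        # ---- elbow ------------------------------------------------------
        stage = "elbow"
        draws = ClusterFitDraws(draws={
            C: within_cluster_distance_posterior(
                rm, fits[C], votes[C],
                n_draws=min(config.n_fit_draws, fits[C].n_stored),
                seed=_stage_rng_seed(config.seed, "elbow", C))
            for C in range(e_lo, e_hi + 1)
        })
        elbow = elbow_summary(draws)
        suggestion, drop_table = suggest_c(draws)
        elbow.to_csv(out / "elbow_summary.tsv", sep="\t", index=False)
        drop_table.to_csv(out / "elbow_drops.tsv", sep="\t", index=False)
        manifest["outputs"] += ["elbow_summary.tsv", "elbow_drops.tsv"]
        manifest["suggested_C"] = int(suggestion)
        if config.make_plots:
            ax = plot_elbow(draws)
            ax.figure.savefig(out / "elbow.png", dpi=120)
            plt.close(ax.figure)
            manifest["outputs"].append("elbow.png")

        # ---- stability --------------------------------------------------
        stage = "stability"
        S = colocalization_matrix(StabilityAssignments(labels={
            C: votes[C] for C in range(s_lo, s_hi + 1)}))
        pd.DataFrame(S.S, index=rm.sample_ids, columns=rm.sample_ids).to_csv(
            out / "colocalization.tsv", sep="\t", index_label="sample_id")
        manifest["outputs"].append("colocalization.tsv")
        if config.make_plots:
            ax = plot_colocalization(S)
            ax.figure.savefig(out / "colocalization.png", dpi=120)
            plt.close(ax.figure)
            manifest["outputs"].append("colocalization.png")

        # ---- gene lists at the chosen C ---------------------------------
        stage = "gene-lists"
        C_final = config.final_c or suggestion
        manifest["final_C"] = int(C_final)
        chain = fits[C_final] if C_final in fits else _fit_one(rm, C_final,
                                                               config, table)
        k_grid = [k for k in config.k_grid if k <= n] or [min(n, 10)]
        for k in k_grid:
            glt = gene_list_table(chain, k=k, min_prob=config.exploration_min_prob,
                                  gene_ids=rm.gene_ids)
            for c, df in glt.tables.items():
                df.to_csv(out / f"genelist_C{C_final}_cluster{c}_k{k}.tsv",
                          sep="\t", index=False)
        manifest["outputs"].append(f"genelist_C{C_final}_cluster*_k*.tsv")
        if config.make_plots:
            k_show = max(k_grid)
            ax = plot_topk_profiles(
                {c: topk_probability(chain, c, k_show) for c in range(chain.C)},
                k=k_show, min_prob=config.exploration_min_prob)
            ax.figure.savefig(out / "topk_profiles.png", dpi=120)
            plt.close(ax.figure)
            manifest["outputs"].append("topk_profiles.png")

        # ---- enrichment -------------------------------------------------
        if config.gmt_path:
            stage = "enrichment"
            collection = read_gmt(config.gmt_path)
            k_enr = min(config.enrichment_k, n)
            for c in range(chain.C):
                probs = topk_probability(chain, c, k_enr)
                genes = [g for g, p in zip(rm.gene_ids, probs)
                         if p >= config.enrichment_min_prob]
                if not genes:
                    continue
                res = hypergeom_enrichment(genes, collection, rm.gene_ids)
                res.to_csv(out / f"enrichment_cluster{c}.tsv", sep="\t",
                           index=False)
                if config.make_plots:
                    ax = plot_enrichment(res)
                    ax.figure.savefig(out / f"enrichment_cluster{c}.png",
                                      dpi=120)
                    plt.close(ax.figure)
            manifest["outputs"].append("enrichment_cluster*.tsv")

        # ---- label comparisons ------------------------------------------
        if config.label_paths:
            stage = "label-comparison"
            from .enrichment import compare_labelings
            ours = pd.Series(votes[C_final], index=rm.sample_ids).astype(str)
            for name, path in config.label_paths.items():
                theirs = read_labels(path)
                cmp_res = compare_labelings(ours, theirs)
                cmp_res.formatted().to_csv(
                    out / f"comparison_{name}.tsv", sep="\t",
                    index_label="cluster")
                with open(out / f"comparison_{name}_test.json", "w") as fh:
                    json.dump({"chi2": cmp_res.chi2, "df": cmp_res.df,
                               "p_value": cmp_res.p_value,
                               "n_dropped": cmp_res.n_dropped}, fh, indent=1)
            manifest["outputs"].append("comparison_*.tsv")

        stage = "manifest"
        manifest["stages"] = ["input", "fit", "elbow", "stability",
                              "gene-lists"] \
            + (["enrichment"] if config.gmt_path else []) \
            + (["label-comparison"] if config.label_paths else [])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
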