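# mallowsmix

Bayesian clustering of samples by their within-sample gene rankings,
using a mixture of Mallows models.

## Why ranks?

Joint analysis of expression cohorts that span tissues, platforms or
batches is dogged by scale heterogeneity: absolute measurements are not
comparable, but the *order* of genes within a sample is.  `mallowsmix`
converts each sample's expression profile into a full ranking of the n
analyzed genes (rank 1 = most expressed) and clusters the rankings with a
C-component Mallows mixture,

P(R_j | z_j = c) = Z_n(α_c)⁻¹ · exp( −α_c · d(R_j, ρ_c) / n ),

where ρ_c is the cluster's consensus gene ranking, α_c its precision-like
scale, d the Spearman footrule Σ_i |r_i − s_i|, and z_j the latent cluster
label of sample j.  A Metropolis–Hastings MCMC samples the joint
posterior, so every downstream summary — cluster assignments, the number
of clusters, the genes that characterize each cluster — comes with
uncertainty attached.  It is aimed at transcriptomics (bulk or
single-cell pseudobulk) on pre-selected gene panels of up to ~a thousand
genes.

The package provides the full analysis chain:

* `io_ranks` — expression tables → validated full rankings (explicit tie
  policy, missing data refused rather than guessed);
* `mallows` — footrule distance, exact partition function for small n and
  a thermodynamic-integration estimate beyond, pmf, samplers;
* `mixture` — the mixture MCMC (Gibbs labels, conjugate weights,
  random-walk α, leap-and-shift consensus moves), relabeling,
  diagnostics;
* `selection` — posterior within-cluster sum of distances over a range of
  C, elbow boxplots, an advisory suggestion rule;
* `stability` — majority votes and the co-localization matrix S across C;
* `gene_lists` — posterior P(gene in cluster's top-k) lists,
  co-occurrence across clusters with KS tests;
* `enrichment` — hypergeometric over-representation with a custom
  background, Benjamini–Hochberg correction, chi-square contingency
  comparisons against external labelings;
* `synthetic` — Mallows-mixture cohorts with known truth, expression
  rendering, planted gene-set fixtures;
* `pipeline` / `cli` — the orchestrated end-to-end run, reproducible from
  one seed.

## Worked example

The scripts under `analysis/` run the whole method on a synthetic cohort
with known truth — 300 samples, 20 genes, 3 mixture components at α = 10:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_and_select_c.py
python analysis/03_stability.py
python analysis/04_gene_lists_enrichment.py
python analysis/05_label_comparisons.py
```

Output of the fitting and selection step:

```
C=1: median fit 23790, acceptance ~{'alpha': 0.26, 'rho': 0.11}
C=2: median fit 17218, acceptance ~{'alpha': 0.3, 'rho': 0.07}
C=3: median fit 7770, acceptance ~{'alpha': 0.24, 'rho': 0.01}
C=4: median fit 7770, acceptance ~{'alpha': 0.22, 'rho': 0.02}
C=5: median fit 7732, acceptance ~{'alpha': 0.96, 'rho': 1.0}
C=6: median fit 7718, acceptance ~{'alpha': 0.61, 'rho': 0.24}
elbow suggests C = 3 (the fit measure plateaus beyond it)
```

The "fit" is the posterior median within-cluster sum of footrule
distances: it halves while real structure is being split apart and goes
flat once C exceeds the true 3 (the C=5 acceptance rates near 1 belong to
empty clusters sampling their priors).  The stability and comparison
steps then report

```
S over C=2..6: mean co-clustering 0.986 within true clusters vs 0.071 between
C=3 majority vote vs truth: adjusted Rand index 1.000
cluster 0: strict list of 10 genes; significant sets ['enriched_cluster1']
```

i.e. samples from the same true component are always co-clustered as C
varies, the hard partition at C = 3 matches the truth exactly, and each
cluster's high-confidence gene list (P(top-10) ≥ 0.8) recovers exactly
the gene set planted for its matching true component.  The final step
recomputes chi-square association tests on bundled published
cross-tabulations of rank-based tumor clusters against known cancer
subtype classifications (squamous, kidney, breast), e.g.

```
squamous_vs_integrative: chi2 = 102.13, df = 6, p = 9.02e-20
kirc_vs_mrna: chi2 = 160.14, df = 3, p = 1.71e-34
```

The same analysis runs from the command line (`mallowsmix simulate`,
`rank`, `fit`, `elbow`, `stability`, `toplists`, `enrich`, `compare`) or
as one orchestrated, seed-reproducible pipeline:

```bash
mallowsmix run-all config.yaml
```

See `docs/methods.md` for the model, priors, the partition-function
strategy, and what the synthetic benchmark does and does not demonstrate.

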