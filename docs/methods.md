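# Methods

## Model

Each sample j contributes a full ranking R_j of the n analyzed genes
(rank 1 = most highly expressed in that sample).  Rankings are modeled by
a finite mixture of Mallows distributions with the Spearman footrule
distance d(r, s) = Σ_i |r_i − s_i|:

    P(R_j | z_j = c) = exp(−α_c · d(R_j, ρ_c) / n) / Z_n(α_c)

with per-cluster consensus ranking ρ_c (a permutation of 1..n), scale
α_c ≥ 0 (precision-like: larger α concentrates mass near ρ_c), latent
labels z_j ∈ {1..C} and Dirichlet-distributed mixing weights.  The α/n
scaling in the exponent is part of the model definition, so reported α
values are comparable across n.  Because the footrule is right-invariant,
Z_n depends on α only — consensus updates never touch the partition
function, which is what makes the consensus chain cheap.

The likelihood factorizes per sample as written above; when a displayed
mixture likelihood is instead written with a sum over all samples inside a
per-sample product, that form double-counts and is not implementable — the
factorized form is the one consistent with the single-cluster likelihood
and is what this package implements.

Priors: ρ_c uniform on the permutation space; α_c ~ Exponential(rate λ,
default 0.1, i.e. a weakly informative prior with mean 10); weights ~
symmetric Dirichlet(ψ, default 10, discouraging spurious empty
components).  All are configurable through `PriorSpec`.

## Partition function

* n ≤ 8 (`PartitionTable.exact`): the distribution of footrule distances
  from a fixed reference is enumerated once (n! permutations), and
  log Z_n(α) = log Σ_d N(d) e^{−αd/n} is evaluated exactly at any α.
* n > 8 (`PartitionTable.estimate`): thermodynamic integration of
  d log Z_n/dα = −E_α[d]/n.  E_α[d] is estimated on a dense α grid
  (201 points on [0, 50]) by the leap-and-shift Metropolis chain — which
  needs no normalizing constant — warm-started from point to point
  (20 000 steps kept per point after a 25% re-adaptation discard), then
  cumulatively trapezoid-integrated from the exact anchor
  log Z_n(0) = log n! with the exact uniform mean E_0[d] = (n²−1)/3.
  Monotone (PCHIP) interpolation serves values between grid points;
  evaluation outside the grid is an error rather than an extrapolation.

  Naive importance sampling over *uniform* permutations was rejected: for
  moderate α the summand is dominated by permutations near ρ that uniform
  draws essentially never produce (at n = 20, α = 10 a typical uniform
  draw contributes e^{−66} while d = 0 contributes e^0), so the estimator's
  relative error is astronomically large.  Thermodynamic integration
  instead averages a bounded, smooth integrand under the correct measure
  at every α.  Validated against exact enumeration at n = 7: absolute
  log Z error ≲ 0.03 over α ∈ [0, 50].

## MCMC

One sweep updates, in order: labels z_j (Gibbs draw from the categorical
posterior), weights (conjugate Dirichlet), each α_c (Gaussian random walk
on log α with the exponential prior and log-transform Jacobian; proposals
outside the partition grid are rejected), and each ρ_c (leap-and-shift).

Leap-and-shift: pick an item uniformly, move its rank to a uniform choice
within ±L (default L = max(1, n/20)), shift the intervening items by one.
For a leap of 1 the move is an adjacent-rank swap reachable from either
involved item, and the forward and backward total proposal probabilities
coincide (log ratio exactly 0); for leaps ≥ 2 the ratio is the log ratio
of the two boundary-clipped window sizes.  The proposal distribution and
ratio are verified in the tests against a brute-force enumeration of the
mechanism.

Initialization: labels uniform at random, ρ_c drawn from the observed
rankings (data-informed starts shorten burn-in), α_c = 1.  Defaults:
50% burn-in, no thinning.  Empty clusters need no special casing: with no
members the α and ρ updates reduce exactly to prior sampling.

Label switching is undone after the run by greedily matching every stored
iteration's clusters to the maximum-likelihood iteration, by minimal total
footrule distance between consensus rankings; the matching is applied
consistently to ρ, α, z and weights, and leaves every iteration's
likelihood unchanged.  Hard assignments are per-sample modal labels over
the relabeled chain (ties to the smallest index).

The standalone Mallows sampler (used by the synthetic generator) draws
from the exact enumerated pmf for n ≤ 8 and otherwise runs the same
Metropolis chain with burn-in 1000·n and thinning 10·n steps, the latter
chosen so that successive draws are effectively independent (the
goodness-of-fit calibration in the tests is sensitive to residual
autocorrelation).

## Choosing C, stability

For each candidate C, 1000 posterior realizations of the within-cluster
sum of distances Σ_j d(R_j, ρ_{z̄_j}) are drawn (states subsampled
uniformly without replacement; majority-vote labels held fixed) and
summarized as boxplots (quartiles by linear interpolation; Tukey 1.5·IQR
whiskers).  `suggest_c` returns the largest C whose relative drop in the
posterior median versus C−1 exceeds 2%; the rule is advisory — the elbow
is ultimately a judgment call, so the pipeline records the full table and
the suggestion rather than silently deciding.

Stability: S_ij is the fraction of C values in a contiguous range
(default 10..30, smaller in the synthetic study) at which samples i and j
share a majority-vote cluster.  S depends only on the partitions, not on
cluster labels, and every entry lies on the 1/(C_M−C_m+1) grid.

## Gene lists and enrichment

P(ρ_ic ≤ k | data) is the fraction of stored iterations in which gene i
is in cluster c's top k; "top-k" is rank ≤ k, inclusive.  Because every
posterior state is a full permutation, these probabilities sum to exactly
k per cluster — an identity the tests assert to 1e−12.  Lists use
threshold ≥ 0.01 for exploration and ≥ 0.80 (at k = 100) as enrichment
input; both thresholds are inclusive ("at least"), and k defaults to the
grid 10, 20, …, 100 capped at n.

Co-occurrence counts (in how many other clusters a cluster's top-ranked
gene is also top-ranked) are compared between a focal cluster and the
counts pooled over all other clusters by a one-sided two-sample
Kolmogorov–Smirnov test, reporting the dominant direction.  The pooled
reference is an interpretation: the natural "expected under random
variation" baseline available without a permutation scheme.

Enrichment is the one-sided upper-tail hypergeometric test
P(X ≥ overlap), each set first intersected with the explicit background
universe (the analyzed gene set), with Benjamini–Hochberg correction
across sets and significance at adjusted p < 0.05.  A gene list not
contained in the background is an error, not a warning.  Fold enrichment
is (overlap/list size)/(effective set size/background size) — the
standard frequency ratio, stated here because conventions vary.

Label comparisons use Pearson's chi-square without continuity correction
on the cross-tabulation, with percentages of the grand total to one
decimal.  An optional `min_expected` drops categories whose expected
counts fall below a threshold before testing (the full table is still
reported); for the bundled squamous-vs-integrative table, dropping
columns with expected counts < 5 — exactly the four sparse integrative
clusters — reproduces the published p-value of 9.02e-20, while the full
3×8 table gives 1.50e-20, so the published analysis evidently restricted
the test to the dense columns.

## Synthetic data

The generator draws labels from the mixing weights and rankings from the
matching Mallows components — the exact generative counterpart of the
fitted model.  The default scenario is N = 300 samples, n = 20 genes,
C = 3, α = 10, equal weights, high separation (min pairwise consensus
footrule ≥ n²/4, obtained by rejection-sampling random permutations,
whose expected pairwise distance ~n²/3 makes the threshold cheap to
reach).  The scenario is sized so the full pipeline runs in minutes while
α = 10 keeps the components concentrated enough for essentially exact
recovery; a cohort-scale run (thousands of samples, ~1200 genes) is
generable with the same functions.

Expression rendering assigns a strictly decreasing geometric value per
rank, then optionally applies a log-normal per-sample scale factor (a
monotone transform emulating library-size heterogeneity — it must not and
does not change ranks), injects ties by copying values within a sample,
and masks cells as missing.  What this does **not** emulate: count noise
that perturbs the rank order itself, gene–gene correlation, or
platform-specific distributions.  Passing tests therefore show that the
inference machinery is correct under the model's own assumptions, not
that real cohorts satisfy those assumptions.

Gene-set fixtures plant one enriched set per cluster (by default the
cluster's true top-10 genes, size 10) plus uniform null sets.  With a
20-gene universe the hypergeometric tail is granular: the fully planted
set reaches p ≈ 5e−6 (and still p ≈ 6e−5 if the fitted list drops one
boundary gene), surviving Benjamini–Hochberg correction across the ~20
null sets, while null sets essentially never clear 0.05.  Partially
planted sets (the ``enriched_fraction`` knob) lose that robustness
quickly: at 90% planting, a single boundary-gene disagreement between
the fitted list and the truth already lands above the corrected 0.05
line — the analysis behind the fully planted default.

## Numerical and degenerate-input choices

* Ties in expression are broken randomly (seeded, mandatory seed) because
  the likelihood needs full permutations; a "stable" first-occurrence
  policy exists for deterministic tests.  Missing entries are refused,
  not imputed: imputation is a preprocessing decision the caller must own.
* Majority-vote ties break to the smallest cluster index; gene-list ties
  break by gene id; greedy relabel matching resolves distance ties by
  scan order.  All deterministic.
* Orientation of delimited tables is an explicit flag; there is no
  auto-detection.
* Gene subsetting re-ranks the retained columns by relative order
  (subsetting rank values directly would break the permutation
  invariant).
* Every stochastic stage of the pipeline derives its seed from the single
  configured seed plus a CRC of the stage name, so reruns are
  byte-identical and per-C fits are independent (no warm starts across C
  — the method is deliberately nonhierarchical).

## Problem sizes used in the checked analyses

Partition/pmf exactness: n ≤ 7 against full enumeration.  Sampler
calibration: n = 5, 50 000 draws.  Detailed-balance check: n = 4, N = 30,
C = 1, 30 000 sweeps against the enumerated posterior with α integrated
out numerically.  Recovery and elbow scan: the default scenario over
C = 1..6, 2000–2200 sweeps per fit.  End-to-end pipeline: the default
scenario with planted gene sets.

## Known limitations

* Exact partition values stop at n = 8; beyond that, log Z carries the
  (small, validated) thermodynamic-integration error, which enters α
  inference but cancels entirely from consensus and label updates.
* Full rankings only: no partial or top-t rankings, no pairwise
  preferences, no tied observed ranks after the tie-breaking step.
* Footrule only; Kendall or Spearman-ρ² variants would need their own
  partition machinery.
* The elbow rule is a heuristic; nothing replaces inspecting the
  boxplots.
* MCMC cost grows with n and C; around a thousand genes is the practical
  ceiling at cohort scale, consistent with the method's intended use on
  pre-selected gene panels.
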