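# Methods

This note documents the statistical models implemented in `triomics`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Overview

The toolkit integrates genotype and metabolomics data for
mother–offspring pairs in four stages:

1. **Metabotype association scan** — per-metabolite GWAS-style linear
   regression of each metabolite on each additive SNP dosage plus
   covariates, retaining SNP×metabolite pairs with p < 10⁻⁷·⁵ and
   greedily LD-trimming the significant SNPs per metabolite.
2. **Penalized Bayesian-network estimation** — a sparse Gaussian DAG
   over typed nodes (maternal/newborn genotypes, metabolites,
   phenotypes), constrained by a biological-ordering blocklist and
   estimated along a decreasing penalty path λ = 15 … 1.
3. **Mediation-path extraction** — all shortest directed paths from a
   maternal feature to a newborn outcome in the least-penalized
   network, with contiguous-subpath exclusion and a minimum of three
   nodes.
4. **Serial mediation modeling** — PROCESS-Model-6-style chains fit by
   OLS with covariates in every equation, bootstrap inference on the
   serial indirect effect, Benjamini–Hochberg discovery on a training
   split and nominal replication on a held-out validation split.

A synthetic cohort generator with a known linear-Gaussian ground truth
ties the stages together so that every inferential claim can be checked
against closed forms or brute-force enumeration.

## The network model and its score

A Bayesian network over nodes x₁…x_p factors the joint density into
per-node conditionals.  For conditional Gaussians with coefficient
matrix B (B_ij the effect of node i on child j) and profiled
conditional variances σ̂²_j = RSS_j/n, the penalized score is

    S(B; λ) = Σ_j (n/2)(1 + log 2π·RSS_j/n) + n Σ_{ij} pen_μ(|B_ij|),
    μ = λ/√n,

with pen either the lasso or (default) the minimax concave penalty MCP
with γ = 2, which de-biases large coefficients while keeping the same
entry threshold at zero.  Genotype dosages (0/1/2) enter as ordinary
continuous columns — the same conditional-Gaussian approximation that
underlies additive-coding GWAS; this is an approximation, not a claim
that dosages are Gaussian.

### Why μ = λ/√n

Penalty units for this family of learners are package-internal and not
portable, so only the grid shape (integer λ from 15 down to 1) is
meaningful.  We give the printed grid a stable statistical meaning: on
standardized data the stationarity condition for an edge at zero is
|√n · r| > λ, where r is the partial correlation of the candidate
parent with the child's current residual.  λ therefore acts as a
|z|-statistic threshold — λ = 15 keeps only overwhelming signals and
λ = 1 admits essentially everything — and the same grid is equally
meaningful at n = 500 or n = 2000.  Networks grow monotonically in
density as λ decreases, reproducing the sparse-to-dense growth the
method is designed to visualize.

### Optimization

Estimation is block-cyclic coordinate descent over ordered node pairs
(i, j): both potential coefficients are updated jointly with at most
one nonzero, skipping blocklisted directions and any update that would
close a directed cycle.  Each scalar subproblem minimizes
(n/2)log RSS(β) + n·pen_μ(|β|) exactly by majorize–minimize: the
concave log term is bounded by its tangent, giving a penalized
quadratic with a closed-form (soft-threshold / MCP) minimizer; the
bound guarantees the true score never increases.  Ties between the two
directions are broken deterministically (sparser state first, then the
lexicographically lower (parent, child) direction), and the pair sweep
order is fixed lexicographic, so results are reproducible bit-for-bit.

Because the profiled-Gaussian score is identical across
Markov-equivalent DAGs, single-coefficient moves can converge to a
wrongly oriented local optimum whose repair requires changing two
coefficients at once (e.g. turning a fork into a collider).  Two
deterministic safeguards address this.  First, a *structure repair*
phase after the sweeps converge: every estimated edge is tentatively
reversed with a full penalized refit of the two affected nodes, and
every pair of edges sharing a node is tentatively double-reversed with
refits of all affected nodes; the best strictly score-decreasing move
is applied and the sweeps re-run, until no move helps.  Second,
cold-started fits are *multi-started*: descent runs from the empty
graph, from a continuation pass (λ_max down to the target λ), and from
eight inits built by per-node penalized regression along fixed random
topological orders; the best-scoring result is returned.  All starts
are seeded with package constants, so results remain bit-reproducible.
On exhaustively enumerable problems (all 543 labelled DAGs on four
nodes, each scored by independent per-structure penalized regressions)
the learner reaches the global optimum in ~95–100 % of strong-signal
instances and, by construction, never reports a score below it.

Solution paths are estimated from the largest λ down, warm-starting
each model from the previous one (warm-started fits run a single
descent plus repair).

### The blocklist and identifiability

Eleven a-priori rules exclude biologically impossible directions:
offspring SNPs cannot cause maternal SNPs, phenotypes or maternal
metabolites; newborn outcomes and cord metabolites cannot cause either
parent's SNPs; maternal metabolites and phenotypes cannot cause SNPs;
and SNP→SNP edges are forbidden across chromosomes.  Beyond biology,
the blocklist is what makes orientation estimable: purely observational
Gaussian likelihoods identify structure only up to Markov equivalence,
and direction is recovered exactly where the blocklist or a collider
(v-structure) pins it.  The packaged 12-node benchmark graph is
deliberately constructed so that every true edge is oriented by one of
those two mechanisms; on graphs without such anchoring, reported edge
directions within an equivalence class follow the deterministic
tie-break and should not be over-interpreted.

## Association scan

Each SNP–metabolite pair is fit by OLS (statsmodels) of the metabolite
on intercept + dosage + covariates; the per-allele effect, classical
SE, t statistic and two-sided p-value are recorded, dropping rows with
missing outcomes.  The retention threshold defaults to p < 10⁻⁷·⁵,
deliberately slightly more inclusive than the conventional 10⁻⁸
because the penalized network provides a second, stronger selection.
LD trimming is greedy in ascending p: a SNP is kept iff its squared
dosage correlation with every already-kept SNP is below the threshold
(default r² = 0.5, configurable — published hit counts depend on this
unstated constant).  Trimming operates on the full significant set per
metabolite rather than a sliding window.

## Path extraction

Shortest directed paths (unweighted edge count, all ties kept) are
enumerated from every maternal feature node (MG/MM/MP) to every
newborn outcome node (NP with role `outcome`) in the λ = 1 network.
The pooled candidate set then drops any path that occurs as a
contiguous ordered slice of a longer candidate, and any path with
fewer than three nodes.  Output order is deterministic (length, then
node-id sequence).

## Serial mediation

For a path X → M₁ → … → M_k → Y, each mediator is regressed on X and
all earlier mediators, the outcome on X and all mediators, and the
outcome on X alone (all equations include the configured covariates):

    IDE = a₁·d₂₁·…·b_k,  DE = X-coefficient of the full outcome
    equation,  TE = X-coefficient of the reduced form,  PM = IDE/TE.

PM uses the total-effect denominator, which is why it can exceed 100 %
or be negative.  Inference resamples individuals with replacement
(default 1000 replicates; the benchmarks use 500): the IDE standard
error is the replicate standard deviation, the CI is the 2.5/97.5
percentile interval, and the p-value is the two-sided normal
approximation 2Φ(−|IDE|/SE).  The point estimate comes from the full
sample and does not depend on the replicate count.  Replicates with
singular designs are dropped and counted; more than 10 % failures
raises an error.

One numerical convention: an exactly singular equation whose
least-squares residual is zero (a deterministic equation, as in
noiseless fixtures) is resolved by attributing shared variance to the
rightmost independent predictors — mediator priority, i.e. the
full-mediation reading of a noiseless chain — while a singular
equation with nonzero residual raises a singular-design error.

Discovery/replication: candidate paths are screened on the training
cohort with Benjamini–Hochberg adjustment of IDE p-values *within each
analysis family* (fasting-network and 1-hr-network paths are adjusted
separately); survivors require adjusted p < 0.05 and PM > 0, and are
validated on the held-out cohort at nominal p < 0.05 with PM > 0 (the
PM requirement can be switched off).

## Synthetic cohort generator

The generator emulates exactly the dependency structure the network
model assumes:

- **Trio genetics.** Maternal dosages are Binomial(2, MAF) under
  Hardy–Weinberg; the offspring receives one uniformly chosen maternal
  allele plus one paternal allele drawn from the population frequency
  (fathers are not modeled as nodes, matching the study design).  The
  implied maternal→offspring linear coefficient is exactly 0.5 and the
  dosage correlation exactly ½, which the benchmarks verify.
- **Omics and phenotypes.** Non-genotype nodes are generated in
  topological order as intercept + Σ coefficient·parent + N(0, σ),
  so the population covariance is (I−B)⁻ᵀ Ω (I−B)⁻¹ in closed form
  (with Ω entries 2pq for maternal SNPs and 1.5pq for transmitted
  offspring SNPs).  Ground-truth serial indirect effects are products
  of path coefficients.
- **Covariates and strata.** Covariates are independent standard
  normals by default (the study adjusts for covariates but does not
  model them as nodes), with an optional confounding hook.  Ancestry
  strata are four labels with Dirichlet-sampled proportions — the
  study's four ancestry groups without claiming their sizes.
- **Split.** The train/validation split is stratified by ancestry with
  round-half-up per stratum at the default fraction 2/3.  On a single
  stratum of 1385 pairs this gives 923 training pairs; the published
  924 reflects per-stratum arithmetic that is not recoverable.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (loci are unlinked), non-Gaussian or heavy-tailed metabolite
distributions, batch effects, missingness mechanisms, population
structure, or covariate–omics confounding (unless requested).  Passing
benchmarks therefore demonstrate correctness of the estimators under
the stated linear-Gaussian model, not robustness to real-data
pathologies.

## Benchmark problem sizes

The packaged benchmarks (also recomputed by `scripts/acceptance.py`)
use: 20 four-node problems at n = 500 against exhaustive enumeration;
the 12-node typed graph at n = 2000 with |coefficients| = 0.8 over the
full 15…1 path (success = structural Hamming distance ≤ 2 at some λ);
100 randomized constraint checks; 100 regression-oracle instances plus
10 000 permutation replicates for null calibration; 100 random typed
DAGs for path-extraction equivalence; 200 coverage replicates and 1000
null replicates at n = 500 with 500 bootstrap draws for the mediation
estimator (true IDE 0.125 from a = d = b = 0.5); and 50 replicates of
one planted pathway among 50 nulls at n_train = 900 / n_valid = 450
for the two-stage protocol.  The mediation null sets a₁ = 0 with
d = b = 0.5, under which the IDE estimate is asymptotically normal and
its p-value uniform; under the complete null (all coefficients zero)
the product statistic is not normal and no p-value construction of
this form is calibrated.

## Other numerical choices and limitations

- Data are standardized to zero mean and unit variance before network
  learning (penalties are scale-sensitive); reported edge weights are
  on the standardized scale.
- Phenotype transforms (log₁₀ fasting glucose, √1-hr glucose, √sum of
  skinfolds, log₁₀ cord glucose/C-peptide in the motivating study) are
  applied through a configurable transform table, not hard-coded.
- Metabolite preprocessing drops columns above a missingness threshold
  (0.1 targeted / 0.2 non-targeted in the motivating study; the
  threshold is a parameter) and imputes remaining gaps with the column
  minimum, reflecting detection-limit missingness.
- Interactive network animation is replaced by per-λ GraphML plus
  static PNG frames with a stable palette (genotypes green, outcomes
  grey, metabolites colored by compound class; maternal nodes square,
  offspring round); frame index 1 corresponds to the largest λ.
- The learner treats every node's conditional as Gaussian; discrete
  outcomes, interaction terms, latent confounding and
  parallel-plus-serial mediation are out of scope.
- Single-λ model selection is deliberately absent: the intended use is
  inspection of the whole solution path.
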