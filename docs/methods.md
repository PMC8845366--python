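# Methods

This note documents the models and procedures implemented in `epifem`,
the numerical choices behind them, what the synthetic benchmark does and
does not emulate, and the design decisions taken where the problem was
genuinely open.

## Differential statistics

Per gene we fit ordinary least squares of the measurement (promoter mean
beta, or log expression) on an intercept, a disease indicator, and
covariates, then shrink the residual variances with an
empirical-Bayes scaled-inverse-chi-square prior whose hyperparameters
(d₀, s₀²) are estimated by moments matching on the log residual
variances: with d residual degrees of freedom, e_g = log s²_g − ψ(d/2) +
log(d/2) has mean log s₀² + ψ(d₀/2) − log(d₀/2) and excess variance
ψ′(d₀/2); ψ′ is inverted by Newton iteration. The moderated t is
b_g/(u·s̃_g) with s̃²_g = (d₀s₀² + d s²_g)/(d₀+d) on d₀+d degrees of
freedom. With fewer than 10 genes the prior is unreliable and the
implementation falls back to the ordinary t with a warning; `prior_df=0`
disables shrinkage (used to check the OLS oracle, and verified in the
test suite against R limma to 1e-10). Benjamini–Hochberg controls the
FDR throughout; the gene-level significance threshold for module
bookkeeping is FDR < 0.05 (configurable).

Because bulk tissue is a mixture, cell-type fractions enter the designs
as covariates. Fractions sum to one, so only the first k−1 fraction
columns are included alongside the intercept; which fraction is absorbed
is irrelevant to the disease coefficient. Genes with zero residual
variance get t = 0, p = 1 with a warning rather than an error. An
optional per-gene copy-number covariate triggers per-gene designs; a
constant CNV row is dropped so the fit reduces exactly to the unadjusted
model, and `cnv_robustness` reports paired t's, their Pearson
correlation and sign concordance over a gene set.

Cell-type-specific differentially methylated genes use the
fraction-interaction model beta ~ Σ_k f_k + Σ_k f_k·disease without a
global intercept (the f_k sum to one, so the intercept is implicit); the
interaction coefficients are the within-compartment disease effects,
tested with the same variance shrinkage and BH correction per cell type.
Constant fractions make the interactions inestimable and raise a
rank-deficiency error.

## Deconvolution

Reference construction: per cell type, a one-vs-rest moderated-t
comparison on the purified profiles; marker CpGs must pass BH FDR < 0.05
*and* |mean(own) − mean(rest)| above the per-comparison Δ threshold
(default 0.9; individual comparisons can be relaxed, e.g. to 0.875, via
a dict). The reference value is the within-type mean beta, and each CpG
records which comparison(s) selected it. A comparison selecting zero
CpGs is an error naming the comparison.

Fraction estimation (robust partial correlations): per sample, Huber
regression (tuning constant 1.345) of the sample's betas over the
reference CpGs on the reference profiles, with intercept; negative
coefficients are truncated at zero and the remainder renormalized to sum
to one. Betas stay on the [0,1] scale (no M-values). The estimator is
exact on noiseless mixtures, permutation-equivariant in the reference
columns, and in the benchmark recovers Dirichlet(2,2,2) mixtures at beta
noise SD 0.05 with per-type RMSE below 0.01.

## Module discovery

Gene-level integrated statistic: t^(I) = {H(t_DM)H(−t_DE) +
H(−t_DM)H(t_DE)}·|t_DM − t_DE| with H(0) = 0, so a zero statistic never
contributes and concordant directions score zero. Edge weights are the
endpoint averages w_gh = ½(t^(I)_g + t^(I)_h); the Hamiltonian of a gene
set S is E(S) = −Σ_{g<h∈S}(w_gh − γ p_gh) over unordered pairs, with the
configuration-model null p_gh = w_g·w_h·/2W (w_g· the weighted degree, W
the total edge weight; non-edges contribute only the null penalty). γ
defaults to 0.5, which yields modules in the 10–100 size range used as
the size filter. If W = 0 all energies vanish and nothing grows.

**Growth and refinement.** Growth from a seed adds, at each step, the
adjacent gene with the largest energy decrease (ties broken
lexicographically for bit-reproducibility) and stops when the best
candidate no longer raises the size-normalized modularity −E/|S|. The
stop rule deserves emphasis: because each edge weight averages its
endpoint statistics, *any* neighbor of a high-t^(I) member offers an
energy decrease of about t_hot/2 while its configuration-null penalty is
bounded by γ·w_v··Σ_S w_g·/2W, which is far smaller at γ = 0.5 — growth
that stops only when no addition decreases the energy therefore floods
the connected component (no proper subgraph is a local minimum). Holding
out for rising modularity instead keeps the module a hotspot of high
edge-weight density, which is precisely what the method is after, and
energy still decreases strictly at every accepted step.

Two refinement passes follow, both mirrors of the acceptance logic: a
statistic filter removes members (never the seed; seed component kept)
whose own t^(I) is below half the module's mean — a zero-statistic gene
with two hot edges is energetically indistinguishable from a weak
genuine member, but its own statistic is not — and an energy prune
removes members whose marginal contribution to −E falls below half the
modularity, subject to connectivity. Fragments grown from different
seeds inside one hotspot are merged (overlap coefficient > 0.5,
transitively), the union re-filtered and re-pruned, before the 10–100
size filter.

**Significance.** Two permutation tests are provided. The
fixed-membership test permutes the node statistics over the network
(topology fixed), re-derives edge weights and recomputes the module's
modularity on its frozen membership; p = (1 + #{≥ observed})/(1 + runs).
Its p-values are uniform for modules chosen independently of the data
(verified by KS test), but they are *anti-conservative for modules that
were themselves grown to maximize modularity*. `infer_modules` therefore
uses a selection-aware null by default: for each of the 1000
permutations a module is grown from that permutation's top-statistic
seed, and each observed module is compared against the resulting
modularity distribution (computed once per dataset). On null data this
calibration reports essentially no modules; the fixed-membership test
remains available via `null_calibration="fixed"`. Final modules require
mc_p < 0.05; overlapping survivors (Jaccard > 0.5) are deduplicated
keeping the lower energy, and members are flagged DM, DR, DM&DR and
anticorrelated (DM&DR with opposite signs).

All randomness flows from a single integer seed; per-module and
per-stage child seeds are derived by stable hashing, so results are
reproducible bit-for-bit and adding a stage never perturbs another.

## Module scoring

Validation z-scores use the normal/healthy samples' mean and population
SD (divisor n — with 5–6 normals the choice matters; the population
convention is deterministic and slightly conservative). A gene with zero
normal SD (and zero offset) is dropped with a warning. The signed score
averages Sign(t_g)·z_gs over the discovery-significant signature genes
present in the cohort, recording how many were used. The joint
DNAm+expression score averages |z^(M) − z^(R)| over genes that are
significant in both modalities with anti-correlated directions; the DNAm
z-score denominator carries an additive offset calibrated by root
finding so the genome-wide DNAm z SD equals the RNA z SD (the function
is strictly decreasing in the offset; if the target exceeds the SD at
zero offset the calibration clamps to 0 with a warning). The single-cell
variant requires at least 5 signature genes with nonzero variance across
the scored cells; otherwise the module is declared unscoreable.
Saliva-style staged cohorts reuse the signed score with the healthy
controls as the normal reference and pairwise stage-vs-normal tests.

Evaluation: one-tailed Wilcoxon rank-sum (positive group larger), exact
null below a combined n of 25 when untied, otherwise the normal
approximation with continuity and tie correction; AUC = U/(n₁n₂).
`score_with_covariate_adjustment` refits score ~ group + covariate by
OLS (e.g. epithelial fraction) and reports the group t and p; a constant
covariate reduces to the unadjusted test with a warning.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, with
defaults that define the reference study conditions:

* **Network** — preferential attachment (1000 genes, 3 edges per new
  node) with three planted connected modules of sizes 15/20/30 densified
  to internal density 0.35. Planted modules are node-disjoint *and*
  separated by a 1-hop buffer, and densification connects the least
  internally connected pairs first: both are identifiability
  requirements — adjacent or dumbbell-shaped "modules" are not a
  recoverable ground truth for any density-based detector.
* **Cohort** — 50 cases / 50 controls; per-sample
  epithelial/fibroblast/immune fractions ~ Dirichlet(4,2,2); per-gene,
  per-cell-type baseline betas logit-normal around 0.25; planted genes
  draw mid-range epithelial baselines U(0.35, 0.55) so the planted
  ±Δβ = 0.3 (epithelial compartment only, alternating hyper/hypo per
  module) is realizable without clipping; expression shifted |logFC| = 1
  in the opposite direction (anti-correlation at the mean level, the
  construct the integrated statistic rewards). Observed betas are
  fraction-weighted mixtures with logit-normal noise (beta-scale SD
  0.05), exploded to 2 TSS200 + 1 1stExon + 1 TSS1500 probes per gene
  with jitter SD 0.02 to exercise the summarization precedence;
  expression noise SD 0.5. Marker CpGs consistent with the purified
  profiles are mixed into the probe matrix so deconvolution runs on the
  same cohort.
* **Purified profiles** — 6 samples per type, 50 markers per type at
  |Δβ| ≈ 0.95 (half hyper-, half hypomethylated in their own type, as on
  real arrays — this also conditions the reference regression), noise SD
  0.02, plus 500 shared background CpGs.
* **Saliva-like cohort** — stage sizes 65/33/14/51 (N/NDBE/HGD/C);
  epithelial fraction mean rising 0.15 + 0.07·stage; the first planted
  module's promoter betas shift with stage in the epithelial component
  only (full-stage Δβ = 0.25).
* **Single cell** — 4 patients × (112 normal + 147 BE-like) cells
  (~450/~590 total), log-normal-ish baselines, signature genes shifted
  down by 1.5 in BE-like cells, Bernoulli dropout 0.6 by default.

What the benchmark does **not** emulate: probe-level technical artifacts
(type-2 bias, batch), realistic LD-like correlation among CpGs,
immune-subtype structure below the three broad compartments, CNV beyond
an independent Gaussian covariate, and read-count noise in the
single-cell data. Passing tests therefore demonstrate correctness of the
algorithms under the assumed generative structure, not performance on
raw array data — upstream QC and normalization remain the user's
responsibility.

## Problem sizes and runtime

The default benchmark (1000 genes, 100 seeds, 1000 Monte-Carlo
permutations) completes discovery in a few seconds; the full acceptance
run, including the null fixture, 100 cell-type-specific replicates and
all scoring variants, takes well under a minute on one CPU. The test
suite's shared fixtures use a 300-gene version of the same conditions.

## Known limitations

* The greedy growth explores additions around single seeds; hotspots not
  touched by any of the top seeds are invisible (mitigated by using ~100
  seeds).
* The selection-aware null grows one module per permutation (from the
  permutation's top seed); it calibrates the maximum well but is mildly
  conservative for lower-ranked observed modules.
* The deconvolution layer implements the three-compartment reference
  stage only; immune subtypes (a second hierarchical layer) are out of
  scope.
* With very few normal samples the z-score reference is noisy; the
  offset calibration addresses variance inflation for the joint score
  but not bias in the normal mean.
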