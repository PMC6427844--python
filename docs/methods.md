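# Methods

## Model

Cells are indexed n = 1..N, genomic regions m = 1..M, and the observed
CpGs of cell n in region m sit at scaled positions x ∈ [−1, 1] with binary
states y ∈ {0, 1}. The latent methylation profile of region m under
cluster k is Φ(w_mk^T h(x)): a probit-linked generalised linear model on a
fixed design h(x) = (1, rbf_1(x), …, rbf_L(x)). The full hierarchy is

- π ~ Dirichlet(δ₀·1_K), c_n | π ~ Categorical(π)
- τ_k ~ Gamma(α₀, β₀), w_mk | τ_k ~ N(0, τ_k⁻¹ I_D)
- z_nmi | c_n = k ~ N(w_mk^T h(x_nmi), 1), y_nmi = 1[z_nmi > 0]

The augmented variable z replaces the probit likelihood with a Gaussian
one truncated by the observation's sign, making every conditional
conjugate. Bisulfite conversion error is not modelled explicitly; the
generator's probability noise emulates it and the fits tolerate it.

Assumptions worth keeping in mind: regions are modelled independently
given the cluster; a cell belongs to exactly one cluster genome-wide;
within a region all cells of a cluster share one profile; CpG states are
conditionally independent given the profile.

## Variational inference

The mean-field family q(Z) q(C) q(W) q(π) q(τ) is optimised by coordinate
ascent; each factor update is the exact conditional optimum, so the ELBO
is non-decreasing over sweeps (asserted in the tests at relative tolerance
1e-6). Updates per sweep, in fixed order:

1. **q(z_nmi)**: unit-variance Gaussian truncated to (0,∞) if y=1 else
   (−∞,0], centred at the responsibility-weighted predictor
   Σ_k r_nk λ_mk^T h(x). Moments use the log-scale Mills ratio
   (`scipy.special.log_ndtr`), stable beyond |μ| = 30.
2. **q(w_mk)**: Gaussian with precision E[τ_k] I + Σ_n r_nk H_nm^T H_nm and
   mean solving the responsibility-weighted normal equations against E[z].
3. **q(τ_k)**: Gamma(α₀ + MD/2, β₀ + ½ Σ_m E[w_mk^T w_mk]).
4. **q(c_n)**: categorical with log r_nk ∝ ψ(δ_k) − ψ(Σδ) +
   Σ_mi [E[z] h^Tλ_mk − ½((h^Tλ_mk)² + h^T S_mk h)].
5. **q(π)**: Dirichlet(δ₀ + Σ_n r_nk).

E[ln p(Y|Z)] vanishes in the ELBO because each q(z) is truncated
consistently with its observation; the truncation mass enters through the
q(Z) entropy.

Components are never deleted: a component whose expected occupancy
Σ_n r_nk falls below one cell-equivalent is counted as pruned when
reporting the effective number of clusters. This variational pruning is
what performs model selection when the fit starts with a deliberately
generous K.

**Initialisation.** Responsibilities come from k-means on the N×M matrix
of per-region mean rates (missing entries column-mean filled), softened to
0.9/0.1; additional restarts use random Dirichlet responsibilities, and
k-means falls back to random responsibilities if there are fewer distinct
rate rows than K. The fit with the best final ELBO wins, ties to the
earliest restart. All randomness descends from the single `seed`.

**Convergence.** Relative ELBO change < 1e-5 (default), capped at 400
sweeps.

## Priors

- *broad* (default): δ₀ = 0.5, α₀ = 0.5, β₀ = 10. Weakly informative;
  E[τ] = 0.05 favours smooth profiles without forcing them flat.
- *shrinkage*: δ₀ = 1e-6, same Gamma. Near-zero Dirichlet mass per
  component actively empties redundant components; on data with highly
  similar sub-populations it prunes at least as aggressively as the broad
  prior.

The hyperparameter names and the broad/shrinkage distinction are exposed
on the command line (`--prior broad|shrinkage`).

## Basis

Default L = 4 radial basis functions plus an intercept (D = 5), centres at
the interior points of a 5-way equipartition of [−1, 1], width
γ = 1/(2s²) with s the centre spacing so adjacent bumps cross at half
height. L = 0 gives the intercept-only design used by the rate-constrained
mixture. Both L and γ are configurable; D = 5 is flexible enough for the
prototype shapes while keeping each per-region solve a 5×5 system.

## Gibbs sampler

The same joint distribution is sampled through its full conditionals
(truncated-normal z, conjugate Gaussian w given hard assignments, Gamma τ,
categorical c, Dirichlet π). Defaults: burn-in = half the chain,
thinning 5. Weights start at zero with unit precision — a draw from the
prior can start the probit saturated and stall mixing. Empty components
draw their weights from the prior (the conjugate update with no data).
Label switching is not corrected; evaluation either uses ARI (invariant)
or aligns labels through the clustering overlap table. The sampler exists
as a correctness oracle for the variational engine and for small-data
posterior summaries, not as the scalable path.

## Imputation

Predictive probabilities use the Gaussian weight posterior in closed
form: p(y=1) = Σ_k ω_k Φ(h^Tλ_mk / √(1 + h^T S_mk h)). For cells seen in
training, ω_k = r_nk — the cell's cluster was inferred from its training
CpGs, which is precisely how clustering improves imputation; for unseen
cells ω_k = δ_k/Σδ_j (both modes are exposed). Probabilities are clamped
to (1e-10, 1−1e-10) and binarised at 0.5 (configurable threshold).

## Baselines

- **Rate**: per-(cell, region) smoothed training mean (s + 0.5)/(n + 1);
  the pseudo-count keeps degenerate all-0/all-1 regions off the
  probability boundary so ranking metrics remain defined. Uncovered
  regions fall back to the cell's global smoothed mean.
- **Melissa Rate**: the full mixture with the intercept-only basis.
- **GMM**: diagonal-covariance Gaussian mixture, EM implemented here
  (monotone log-likelihood, variance floor 1e-6), on per-region mean
  M-values, M = log₂((r+0.01)/(1−r+0.01)). Missing rate-matrix entries
  are column-mean imputed before the transform. Imputation inverts the
  responsibility-weighted cluster mean M-value back to a rate. An
  optional PCA projection (first components before EM) is provided.
- **BPRMeth (independent)**: per-(cell, region) MAP probit fit with a
  N(0, τ₀⁻¹I) prior, τ₀ = 0.1 fixed (no pooling exists to learn it),
  found by the augmentation EM (truncated-normal E-step, ridge M-step),
  batched across all blocks; cap 500 iterations, warning + last iterate
  on non-convergence.

## Synthetic data generator

The generator is the package's study-conditions definition, not a
convenience fixture. Defaults: N = 200 cells, K = 4 sub-populations with
exact proportions 40/25/20/15% (block assignment, remainder to the largest
cluster, seeded shuffle; a multinomial mode exists behind a flag),
M = 100 regions, up to 50 CpGs per region with Binomial(50, coverage)
observed (coverage 0.4), per-CpG Gaussian noise (sd 0.05) added to the
success probability before the Bernoulli draw, and cluster dissimilarity
0.5 — the fraction of regions whose prototype is redrawn independently per
cluster; the rest share one prototype across clusters. Independent
redraws may coincide by chance, so "dissimilar" regions differ between
any two clusters with probability 1 − 1/P per pair.

The five latent profile prototypes (flat-high, flat-low, rising, falling,
dip) are fixed target predictors projected onto the basis by least
squares; a hook accepts user-supplied weight vectors. They stand in for
profiles that would otherwise be estimated from bulk methylation data, so
the generator is download-free; their diversity, not their specific
shapes, is what the experiments depend on.

What the generator does *not* emulate: read-level coverage structure
(reads covering adjacent CpGs jointly), non-binary intermediate
methylation, chromosome-scale position effects, and cell-specific global
methylation shifts. Passing tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions plus
probability-scale noise — not performance on any real scBS-seq data set.

## Numerical choices

- Truncated-normal moments via log-Mills ratio; E[z²] = 1 + μE[z].
- Responsibilities normalised with log-sum-exp; Dirichlet/Gamma terms via
  `gammaln`/`digamma`; 0·log 0 = 0 via `xlogy`.
- Weight covariances symmetrised after inversion; ELBO uses `slogdet`.
- Ties in restart selection break to the earliest restart; k-means uses a
  seed drawn from the fit's root generator.
- Degenerate inputs: empty (cell, region) blocks contribute nothing to the
  likelihood; datasets with zero observed CpGs are rejected by `fit_vb`
  (the Gibbs sampler accepts them and then targets the prior); regions
  filtered to nothing raise an explicit empty-dataset error with counts.
- Train/test splitting guarantees at least one training CpG per covered
  block so every fitted region has a likelihood.

## Evaluation conventions

AUC is the Mann–Whitney pair statistic computed by midrank summation, so
constant predictors score exactly 0.5 and ties count half. Precision is 0
when nothing is predicted positive and F = 0 when precision + recall = 0.
The PR curve has one point per distinct threshold, descending, classifying
scores ≥ threshold as positive. ARI is computed from the contingency
table; it is symmetric and label-invariant.

## Region preprocessing

Input positions are 1-based (Bismark convention); BED annotations are
0-based half-open and converted at the reader. Duplicate records at one
position are summed before binarisation. Hemi-methylated sites (ratio
exactly 0.5) are dropped; otherwise state = 1[ratio > 0.5]. A cell covers
a region when it has ≥ `min_cpgs` CpGs there (default 10; a pooled
reading is available via `coverage_mode="pooled"` since either
interpretation is defensible); regions must be covered by ≥ 50% of cells
and show non-zero between-cell variance of mean rates (threshold
configurable; the weakest reading — exact equality — is the default).
Minus-strand regions have positions negated so profiles always read
5′→3′.

## Analysis scales

The heavier consistency checks (model selection, clustering accuracy, the
method comparison) run on N = 200 cells and M = 30 regions with one
variational restart per fit — conditions otherwise identical to the
defaults above; at this scale one fit from K = 10 takes ~10 s on one CPU,
and results match the full-size behaviour. `scripts/acceptance.py` uses
the same scale with 3 replicates for model selection and clustering and 2
for the imputation benchmark; the generator-fidelity check uses the full
N = 200, M = 100 default.

## Known limitations

- A cell belongs to one cluster for all regions; gradual or regional
  mixtures of states are approximated through responsibilities.
- Imputation is restricted to regions present during training; no
  genome-wide sliding-window mode.
- The GMM baseline's imputation rule (inverse-M of cluster means) is one
  reasonable choice among several; it is primarily a clustering
  comparator.
- The variational bound can keep two components alive for one true
  cluster under adversarial initialisation; multiple restarts mitigate
  this.
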