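# melissa

Bayesian clustering and imputation of single-cell DNA methylomes.

Single-cell bisulfite sequencing (scBS-seq) measures CpG methylation at
base-pair resolution, but each cell covers only a small fraction of its
CpGs, so most sites are missing and per-region methylation profiles are
noisy. This package addresses both problems at once for analysts working
with scBS-seq / scM&T-seq-style data: it **clusters cells by their
genome-wide methylation patterns** and **imputes the missing CpG states**,
letting each task inform the other.

## Model

For cell *n*, genomic region *m* and CpG *i* at scaled position
*x*<sub>*nmi*</sub> ∈ [−1, 1], the binary methylation state is a Bernoulli
draw through a probit link on a basis-expanded latent profile:

    y_nmi ~ Bern(Φ(w_mk^T h(x_nmi)))     given cell n is in cluster k,

where **h**(x) is an intercept plus radial basis functions and Φ the
standard normal CDF. Cluster structure is a finite Dirichlet mixture:

    π ~ Dir(δ₀),   c_n | π ~ Cat(π),
    τ_k ~ Gamma(α₀, β₀),   w_mk | τ_k ~ N(0, τ_k⁻¹ I),
    z_nmi | c_n = k ~ N(w_mk^T h(x_nmi), 1),   y_nmi = 1[z_nmi > 0].

The augmented Gaussian z makes every conditional conjugate. Inference is
mean-field coordinate-ascent variational Bayes over
q(Z) q(C) q(W) q(π) q(τ) with a monotone evidence lower bound; a Gibbs
sampler for the same joint distribution is included as a cross-check.
Starting the fit with more components than needed, the variational
optimisation empties redundant ones, so the number of occupied components
estimates the number of cell sub-populations. The posterior predictive
probability of an unobserved CpG is a cluster mixture of probit predictive
densities,

    p(y=1) = Σ_k ω_k Φ( h(x)^T λ_mk / √(1 + h(x)^T S_mk h(x)) ),

with ω the cell's responsibilities (or the posterior mixing weights for an
unseen cell).

Also included: the standard comparators (per-cell-region **Rate**, the
rate-constrained mixture **Melissa Rate**, a **GMM on average M-values**,
and independent per-cell-region **BPRMeth** probit profiles), evaluation
metrics (AUC, precision–recall, F-measure, Adjusted Rand Index), readers
for Bismark-style coverage files and BED/TSS annotations, and a synthetic
data generator that reproduces the cluster-structured study conditions
used throughout the tests.

## Worked example

```python
import numpy as np
from melissa import (SyntheticConfig, simulate_dataset, split_train_test,
                     fit_vb, impute_dataset, evaluate_predictions,
                     adjusted_rand_index)

cfg = SyntheticConfig(N=100, M=20, seed=42)     # 4 latent sub-populations
dataset, truth = simulate_dataset(cfg)
train, test = split_train_test(dataset, train_fraction=0.5, seed=42)

fit = fit_vb(train, K=10, seed=42, n_init=1)
print(f"converged after {fit.n_iter} sweeps, ELBO {fit.state.elbo_trace[-1]:.1f}")
print(f"occupied components: {fit.effective_K} (started from K=10)")
print(f"ARI vs generating labels: {adjusted_rand_index(fit.hard_labels, truth.labels):.3f}")

report = evaluate_predictions(impute_dataset(fit, test))
print(f"imputation AUC {report.auc:.3f}, F-measure {report.f_measure:.3f}")
```

prints

```
converged after 60 sweeps, ELBO -5770.5
occupied components: 4 (started from K=10)
ARI vs generating labels: 1.000
imputation AUC 0.960, F-measure 0.913
```

The fit was handed ten components but kept four — the true number of
simulated sub-populations — recovered the generating labels exactly, and
imputed the held-out half of the CpGs with AUC 0.96.

The same workflow is available from the shell:

```sh
melissa simulate --out data/ --n-cells 200 --seed 1
melissa fit --data data/ --out fit.npz --k-init 10 --prior broad
melissa impute --fit fit.npz --data data/ --out preds.tsv
melissa evaluate --predictions preds.tsv --out metrics.json
melissa benchmark --out bench/ --seed 1      # all methods, one table
```

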