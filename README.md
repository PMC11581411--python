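# mvmrset

Multivariable Mendelian randomization (MVMR) with **correlated**
instrumental-variable sets: identify and estimate the direct causal effects
of several co-located gene-expression traits on a disease outcome, using
the genetic variants of a single GWAS locus as instruments even when those
variants are in strong linkage disequilibrium (LD) with each other.

## Who this is for

Statistical geneticists integrating cis-eQTL and GWAS summary statistics to
prioritize causal genes at GWAS loci with *regulatory pleiotropy* — loci
where the same variants are associated with the expression of several
nearby genes, so single-gene MR is confounded by construction and
independent instruments simply do not exist within the locus.

## The model

A locus is a linear structural equation model over instruments
E<sub>1</sub>…E<sub>L</sub> (variants, correlated by LD), exposures
X<sub>1</sub>…X<sub>K</sub> (gene expression), and an outcome Y:

    X_j = sum_l a_lj E_l + U_j,        Y = sum_k c_k X_k + U_Y,

with error covariance Ψ and implied covariance
Σ = (I − C)⁻¹ Ψ (I − Cᵀ)⁻¹. By Wright's path-tracing rule, whenever the
locus contains at least K causal variants the variants form a Brito–Pearl
*instrumental set*, and the direct effects c solve the linear system

    Σ_EX c = Σ_EY,   i.e.   c = (Σ_EXᵀ Σ_EX)⁻¹ Σ_EXᵀ Σ_EY,

regardless of the LD between instruments. Finite-sample estimators form a
generalized-method-of-moments (GMM) family over the empirical covariances:

* **LS** — plug-in least squares ("regression of regression coefficients");
* **GMM(Δ)** — `(Σ̂_EXᵀ Δ Σ̂_EX)⁻¹ Σ̂_EXᵀ Δ Σ̂_EY` for positive-definite Δ;
* **GMM** — the minimum-variance member Δ = Σ̂_EE⁻¹ (the inverse LD
  matrix), identical to two-stage least squares.

The package provides the identification layer (path tracing, d-separation,
instrumental-set certificates), the estimator family with standard errors
and conditional F / rank diagnostics, a locus-construction pipeline
(greedy lead-SNP loci, LD pruning, exposure-set closure, per-tissue or
gene-tissue-pair MVMR, causal calls at |c| ≥ 0.1 with Bonferroni-corrected
p-values), and a simulator that generates binomial genotypes with
Markov-chain LD for every validation scenario.

## Worked example

```python
import numpy as np
from mvmrset import sem, simulate as sim

# identification: two exposures, two instruments at LD r = 0.7
A = np.array([[0.25, 0.12], [0.10, 0.28]])        # instrument effects
lsem = sem.build_mvmr_sem([[1.0, 0.7], [0.7, 1.0]], A, [0.2, 0.6])
S = sem.implied_covariance(lsem)
print(sem.identify_effects(S[:2, 2:4], S[:2, 4]))
# [0.2 0.6]   <- the true direct effects, recovered exactly despite LD

# estimation: overdetermined three-gene locus, 7 instruments, 3 causal
cfg = sim.three_gene_locus_config(n=10_000, reps=200, seed=1)
print(sim.replicate_experiment(cfg, ("LS", "GMM")).summary().round(3))
```

The summary table reports per-estimator, per-exposure mean, bias, SD, RMSE
and rejection rate at α = 0.05:

```
estimator  exposure  true_effect   mean   bias    sd  rmse  reject_rate  reps
       LS         0         0.15  0.131 -0.019 0.327 0.327        0.175   200
       LS         1        -0.05 -0.066 -0.016 0.275 0.275        0.060   200
       LS         2        -0.27 -0.231  0.039 0.363 0.364        0.350   200
      GMM         0         0.15  0.129 -0.021 0.294 0.294        0.180   200
      GMM         1        -0.05 -0.063 -0.013 0.240 0.240        0.060   200
      GMM         2        -0.27 -0.232  0.038 0.306 0.308        0.370   200
```

Both estimators are unbiased (bias within Monte-Carlo error of zero) with
near-identical spread; the three genes share three causal variants, so the
per-gene SDs are large relative to the effects — exactly the conditional
instrument-strength regime the diagnostics flag.

A command-line surface wraps the library:

```bash
mvmrset fixture --out-dir fx --seed 7            # toy eQTL/GWAS/LD tables
mvmrset loci --eqtl fx/eqtl.tsv --gwas fx/gwas.tsv --ld fx/ld.tsv \
        --out-dir run                            # causal-gene predictions
mvmrset simulate --config scenario.yaml          # replicated experiments
```

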