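# Methods

## Model and identification

A genomic locus is modelled as a linear structural equation model (SEM)
over genetic instruments E₁…E_L, exposures X₁…X_K and an outcome Y.
Directed edges carry direct effects (matrix `C`, row = child); bidirected
edges carry error covariances (`Psi`), representing LD between variants or
latent confounding between exposures and outcome. The implied covariance is
Σ = (I − C)⁻¹ Ψ (I − Cᵀ)⁻¹.

`sem.wright_path_sum` implements path tracing: for standardized variables
the covariance of two nodes is the sum over unblocked (collider-free)
simple paths of the product of edge parameters. For unstandardized
variables each path is multiplied by the variance of its root node (the
unique node carrying no arrowhead on the path); a path through a bidirected
edge carries that edge's covariance instead. Path enumeration is exhaustive
over simple paths with a configurable cap (default 100 000 paths) that
fails loudly; locus graphs here have at most a few dozen nodes.
`sem.random_standardized_sem` constructs random SEMs with exact unit
variances (exogenous nodes first, bidirected edges only between exogenous
pairs, error variances solved in topological order); on these models the
path sum and the matrix formula agree to 1e-10, which the test suite uses
as a two-route oracle.

`sem.check_instrumental_set` verifies the three graphical conditions under
which K instruments identify the K exposure→outcome effects even when
correlated: (1) each instrument is a non-descendant of the outcome with an
unblocked path ending in its paired exposure's edge into the outcome;
(2) each instrument is d-separated from the outcome once all
exposure→outcome edges are removed; (3) an ordered compatibility condition
between the chosen paths (later instruments may not appear on earlier
paths, and shared path nodes must be entered head-on from both sides).
Because condition 3 depends on the instrument ordering, all K! orderings
are searched with backtracking over candidate paths for K ≤ 6; beyond that
a most-constrained-first heuristic ordering is used. The canonical
pleiotropic locus (every exposure keeps at least one causal variant)
receives a certificate; a locus whose second variant is only LD-linked to a
single causal variant is refused at condition 3, matching the fact that
Σ_EX is then rank-deficient.

Identification solves Σ_EX c = Σ_EY by least squares; rank decisions use a
relative singular-value tolerance (1e-8 × the largest singular value),
since no meaningful absolute scale exists for population covariances.

## Estimators

All estimators consume `SummaryCovariances` (Σ̂_EX, Σ̂_EY, Σ̂_EE, sample
sizes, ids, optionally Σ̂_XX). The family

    c(Δ) = (Σ̂_EXᵀ Δ Σ̂_EX)⁻¹ Σ̂_EXᵀ Δ Σ̂_EY

contains LS (Δ = I) and the LD-inverse GMM estimator (Δ = Σ̂_EE⁻¹, equal to
two-stage least squares). Matrix inverses are never formed explicitly:
weighted solves go through Cholesky factors and least squares through
`lstsq`. A near-singular LD matrix (condition number above 1e8) triggers a
warning; a numerically singular one raises an error instructing pruning.
On exactly determined systems (square full-rank Σ̂_EX) the whole family
coincides, which the tests assert both algebraically and on random inputs.

Per-allele summary betas convert to standardized-scale covariances via
cov = β·SD(SNP)/SD(trait) with SD(SNP) = √(2·MAF·(1−MAF)) under
Hardy-Weinberg equilibrium; for a log-odds GWAS the trait SD is taken as 1
and estimated effects read as log-odds per SD of expression.

### Scale convention in simulations

The identity Σ_EX c = Σ_EY holds for covariances of *centered* variables on
any scale. Fully standardizing exposures and outcome would rescale the
true coefficients by SD(X)/SD(Y) (a ~5–15% distortion at the simulated
effect sizes), so the simulator estimates on genotype-standardized,
phenotype-centered covariances (`covariances_from_samples(...,
scale_phenotypes=False)`): recovered effects are then on the structural
scale on which the true effects are defined, and the unit outcome-noise
variance makes the default standard-error scale exact. When reading real
summary statistics the standardized convention applies throughout.

## Inference and diagnostics

Standard errors use the asymptotic sandwich
Var(c) = σ²/n · (BᵀΔB)⁻¹ BᵀΔ Σ̂_EE Δ B (BᵀΔB)⁻¹ (collapsing to
σ²/n·(BᵀΣ̂_EE⁻¹B)⁻¹ for the LD-inverse weight), with σ² = 1 by default — a
conservative choice for a standardized outcome; `se_individual` provides
the exact homoskedastic two-stage least-squares errors from one-sample
individual-level data. The two agree within ~7% in one-sample simulations
at n = 2000 (the suite asserts 15%). Two-sample variability from the
exposure cohort is *not* modelled (it requires individual-level data); a
warning is emitted when the two sample sizes differ. P-values are
two-sided normal; the Bonferroni denominator is the number of gene-tissue
combinations actually tested in a run.

Conditional F-statistics follow the two-stage construction: exposure k is
regressed (by instrumented two-stage least squares) on the remaining
exposures, and the F-statistic of the instruments in the regression of the
residual is computed — entirely from summary covariances, with numerator
df L−(K−1) and denominator df n−L−1. With the covariances taken at ddof=0
this reproduces the individual-level computation exactly, which the tests
verify. With one exposure it reduces to the ordinary first-stage F.

`determinacy_check` reports det(Σ̂_EE), a determinant proxy for Σ̂_EX
(det for square, √det of the Gram matrix otherwise), rank, condition
numbers and flags. Under-determination is flagged when the smallest
singular value of Σ̂_EX falls below the sampling-noise floor
2(√L + √K)/√n — the scale of the largest singular value of an L×K matrix
of pure covariance noise — so configurations whose population matrix is
rank-deficient are flagged essentially always while well-identified ones
are not (the suite measures 100% vs 0–2% at n = 10 000).
`weak_instruments` flags a determinant proxy below 0.001 and
`near_singular_LD` a condition number above 1e8; these thresholds mirror
the accept/reject rules of the strong- and weak-instrument generators.

## Simulator

Genotypes are Binomial(2, MAF) counts built from two independent allele
chains. A first-order Markov chain over alleles sets each conditional
success probability to the bivariate-Bernoulli solution matching the
target marginal frequency and the target correlation of each successive
variant pair; genotype-level correlations then equal allele-level ones, and
non-adjacent correlations follow the Markov product r_ij = Π r_k.
Infeasible (MAF, r) pairs are clipped to the Fréchet bound with a warning
(strict mode raises); the built-in locus presets draw (MAF, r) pairs inside
the feasible region, as real LD must be.

Exposures follow X_j | E ~ N(Σ_l a_lj E_l, σ²) on standardized genotypes
and the outcome Y | X ~ N(cᵀX, σ²), with σ² = 1 by default. The
instrument-effect matrix is drawn uniformly inside a strength range
(strong 0.1–0.3, weak 0.001–0.01) with an optional determinant constraint
on its causal block (strong two-instrument scenarios use det > 0.05; a
det > 0.05 floor is unattainable for 3×3 blocks in that entry range, so
the three-gene preset draws unconstrained); in overdetermined scenarios a
random subset of variants is causal and the rest associate with the
exposures only through LD. Scenario presets encode the validation
conditions: a single instrument of strength 0.8 with true effect 0.3; two
correlated instruments with true effects (0.2, 0.6); a three-gene,
seven-instrument locus with three shared causal variants and effects
(0.15, −0.05, −0.27); a two-gene, five-instrument locus with effects
(0.208, −0.294); an under-determined variant with one causal variant for
two exposures; and a hidden-exposure design in which the first gene's
effect varies over [0, 0.4] while estimation drops that gene.

LD-matrix uncertainty is emulated by Wishart draws W ~ W(df, Σ_ref/df)
rescaled to unit diagonal (mean Σ_ref; df = 50 gives a modest
perturbation). Two-sample designs draw separate LD matrices for the
exposure and outcome cohorts with df tied to the cohort sizes and generate
the cohorts independently; cross-cohort summaries combine Σ̂_EX from the
exposure cohort with Σ̂_EY and Σ̂_EE from the outcome cohort (or an
external reference matrix).

`replicate_experiment` derives per-replicate seeds by spawning a
`SeedSequence` from the master seed (counter-based, reproducible,
independent) and tabulates bias, SD, RMSE and rejection rates.

### What the generator does and does not emulate

It reproduces the moments the method consumes — allele frequencies,
successive LD, instrument-exposure-outcome covariances — but not haplotype
block structure, allelic heterogeneity, winner's-curse selection of
instruments, case-control ascertainment, or trans effects. Passing tests
therefore show correctness of identification/estimation under the stated
structural model, not robustness to those real-data features.

## Locus pipeline

Loci are built greedily from eQTL variants passing the GWAS threshold
(default 5×10⁻⁸), sorted by p-value: the lead SNP collects all eQTL
variants on its chromosome within a closed 1-based window (default radius
500 kb) whose |r| with the lead exceeds a floor (default 0.01 — numeric LD
is never exactly zero), and collected SNPs are removed before the next
lead is taken, so loci partition the SNP set. The exposure set is closed
by alternately adding genes sharing any instrument and instruments
associated with any included gene (a fixed point, idempotent). Nearly
identical variants are pruned at r² ≥ 0.95 by default (configurable per
locus), keeping from each clashing pair the SNP with the smaller GWAS
p-value, then the smaller position — a deterministic tie-break that always
retains the lead.

Per-tissue models (or a single gene-tissue-pair model) assemble summary
covariances from harmonized betas: GWAS records are aligned to the eQTL
effect allele, sign-flipping swapped pairs and dropping strand-ambiguous
(A/T, C/G) or irreconcilable records; when the eQTL table carries no
allele columns, alignment is assumed. A gene with no eQTL row for an
instrument contributes a zero covariance (absence = filtered null effect).
Models with fewer instruments than exposures, or with a statistically
rank-deficient Σ̂_EX, are flagged and produce no estimates. A gene-tissue
combination is called causal when |ĉ| ≥ 0.1 — a threshold anchored to the
smallest effect observed among loci where the causal gene is essentially
known — and its p-value passes α/m for the m tests in the run.

The fixture generator writes toy eQTL/GWAS/LD tables by simulating loci
end-to-end and summarizing them with univariate regressions, embedding the
ground truth in a JSON sidecar. Its default cohort (n = 20 000) is sized so
a typical causal variant clears genome-wide significance; by default each
gene gets its own causal variant ("per_gene"), the robustly identifiable
configuration, with a "shared" mode for maximal regulatory pleiotropy.

## Numerical and design choices

* TSV is the single tabular dialect (tab-separated, header, UTF-8, "."
  decimal, `NA` missing and rejected in required numeric fields).
* Rank tolerance 1e-8 (relative); LD condition-number warning at 1e8.
* The determinant floor/ceiling (0.05 / 0.001) of the instrument-matrix
  generator are also the weak-instrument flag thresholds.
* Wishart df below the matrix dimension is an error.
* Genotype standardization uses the empirical SD with denominator n; all
  summary covariances share that convention so algebraic identities hold
  exactly in tests.

## Known limitations

* Just-identified (L = K) IV estimators have no finite moments: empirical
  variances across replicates are dominated by rare near-singular draws,
  especially at high instrument correlation. Spread comparisons in the
  test suite therefore use interquartile ranges where tails would otherwise
  decide the outcome; raw-variance summaries of such scenarios should be
  read with care. At instrument correlation 0.9 versus 0.1 the *central*
  spread grows roughly threefold while the raw variance ratio is
  essentially unbounded.
* With all causal variants shared by all exposures and dense random effect
  matrices, conditional instrument strength is intrinsically low; large
  per-replicate estimator spread in the three-gene preset reflects that
  regime, not an estimator defect.
* Two-sample bias from LD-matrix mismatch is reproduced but not corrected;
  no weak-instrument-robust (Anderson-Rubin) or bootstrap inference is
  provided.
* The pipeline accepts precomputed LD matrices only; it does not compute
  LD from genotype panels, perform colocalization scoring, or convert
  log-odds effects to the liability scale.
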