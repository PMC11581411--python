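"""Scenario simulator for MVMR with correlated instruments.

Generates genotype/exposure/outcome datasets from linear structural models
whose instruments are binomially distributed genetic variants with a
controlled linkage-disequilibrium (LD) structure:

* genotypes are Binomial(2, maf) counts built from two independent allele
  chains; a first-order Markov chain over alleles matches both the target
  minor-allele frequencies and the target correlations between successive
  variants (non-adjacent correlations then follow the Markov product rule);
* exposures follow ``X_j | E ~ Normal(sum_i a_ij E_i, sigma^2)`` with the
  instrument-effect matrix ``A`` drawn randomly inside a strength range,
  optionally under a determinant constraint on its causal block;
* the outcome follows ``Y | X ~ Normal(c' X, sigma^2)``.

Scenario presets mirror the validation experiments for the method: exactly
determined two-instrument/two-exposure systems, overdetermined loci where
only a subset of variants is causal and the rest hang on through LD,
hidden-exposure (horizontal pleiotropy) designs, Wishart-perturbed LD
matrices, and two-sample designs with separate exposure and outcome cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from . import estimators as est

__all__ = [
    "ScenarioConfig",
    "DatasetBundle",
    "ExperimentResult",
    "markov_genotypes",
    "random_instrument_matrix",
    "simulate_dataset",
    "pleiotropy_scenario",
    "wishart_perturb_ld",
    "two_sample_scenario",
    "combine_two_sample_summary",
    "replicate_experiment",
    "single_instrument_config",
    "two_exposure_config",
    "underdetermined_config",
    "three_gene_locus_config",
    "two_gene_locus_config",
]

DIAGRAMS = {
    "single_IV",
    "multi_IV",
    "exact_K",
    "overdetermined",
    "underdetermined",
    "pleiotropy_hidden",
    "two_sample",
}


class InfeasibleConstraintError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the requested constraint."""


@dataclass
class ScenarioConfig:
    """Full generative description of one simulation experiment."""

    diagram: str
    L: int
    K: int
    true_effects: np.ndarray
    instrument_strength_range: tuple[float, float] = (0.1, 0.3)
    ld_alpha: float | None = None
    ld_maf: np.ndarray | None = None
    ld_succ_r: np.ndarray | None = None
    ld_matrix: np.ndarray | None = None
    n_causal: int | None = None
    det_min: float | None = None
    det_max: float | None = None
    n: int = 2000
    n_eqtl: int | None = None
    n_gwas: int | None = None
    reps: int = 1000
    seed: int = 0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.diagram not in DIAGRAMS:
            raise ValueError(f"unknown diagram tag {self.diagram!r}")
        self.true_effects = np.asarray(self.true_effects, dtype=float).ravel()
        if self.true_effects.shape != (self.K,):
            raise ValueError("true_effects length must equal K")
        lo, hi = self.instrument_strength_range
        if lo > hi:
            raise ValueError("instrument_strength_range must be ordered")
        if self.n_causal is None:
            self.n_causal = min(self.K, self.L)
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.ld_maf is not None:
            self.ld_maf = np.asarray(self.ld_maf, dtype=float).ravel()
            if self.ld_maf.shape != (self.L,):
                raise ValueError("ld_maf length must equal L")
            if np.any((self.ld_maf <= 0) | (self.ld_maf >= 0.5)):
                raise ValueError("minor allele frequencies must lie in (0, 0.5)")
        if self.ld_succ_r is not None:
            self.ld_succ_r = np.asarray(self.ld_succ_r, dtype=float).ravel()
            if self.ld_succ_r.shape != (max(self.L - 1, 0),):
                raise ValueError("ld_succ_r length must equal L - 1")
            if np.any(np.abs(self.ld_succ_r) >= 1):
                raise ValueError("successive correlations must lie in (-1, 1)")

    def resolved_ld(self) -> tuple[np.ndarray, np.ndarray]:
        """Target (maf, successive r) for the genotype generator."""
        maf = self.ld_maf if self.ld_maf is not None else np.full(self.L, 0.3)
        if self.ld_succ_r is not None:
            succ = self.ld_succ_r
        elif self.ld_matrix is not None:
            m = np.asarray(self.ld_matrix, dtype=float)
            succ = np.array([m[i, i + 1] for i in range(self.L - 1)])
        elif self.ld_alpha is not None:
            succ = np.full(max(self.L - 1, 0), self.ld_alpha)
        else:
            succ = np.zeros(max(self.L - 1, 0))
        return maf, succ

    def target_ld_matrix(self) -> np.ndarray:
        """Population LD matrix implied by the Markov structure."""
        if self.ld_matrix is not None:
            return np.asarray(self.ld_matrix, dtype=float)
        _, succ = self.resolved_ld()
        m = np.eye(self.L)
        for i in range(self.L):
            for j in range(i + 1, self.L):
                m[i, j] = m[j, i] = float(np.prod(succ[i:j]))
        return m


@dataclass
class DatasetBundle:
    """One simulated dataset with its generating configuration."""

    genotypes: np.ndarray
    exposures: np.ndarray
    outcome: np.ndarray
    truth: ScenarioConfig
    sample_tag: str = "shared"
    instrument_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1 or 2")
        n = self.genotypes.shape[0]
        if self.exposures.shape[0] != n or self.outcome.shape[0] != n:
            raise ValueError("inconsistent sample sizes across arrays")

    def to_summary(self, scale_phenotypes: bool = False) -> est.SummaryCovariances:
        """Summary covariances with standardized genotypes.

        Phenotypes are centered but by default not rescaled, so estimated
        effects stay on the structural scale of the generating model.
        """
        return est.covariances_from_samples(
            self.genotypes, self.exposures, self.outcome,
            scale_phenotypes=scale_phenotypes,
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def markov_genotypes(
    maf: np.ndarray,
    succ_r: np.ndarray,
    n: int,
    seed=None,
    strict: bool = False,
) -> np.ndarray:
    """Sample an n x L genotype matrix with target MAFs and successive LD.

    Each variant is the sum of two independent allele draws; alleles follow
    a Markov chain whose conditional success probabilities are the
    bivariate-Bernoulli solution matching the marginal frequency and the
    target correlation of each successive pair.  Infeasible (maf, r)
    combinations are clipped to the Frechet bounds with a warning (or an
    error in ``strict`` mode).  Correlations between non-adjacent variants
    follow the Markov product of the intermediate successive correlations.
    """
    rng = _as_rng(seed)
    maf = np.asarray(maf, dtype=float).ravel()
    succ_r = np.asarray(succ_r, dtype=float).ravel()
    L = maf.shape[0]
    if succ_r.shape != (max(L - 1, 0),):
        raise ValueError("succ_r must have length L - 1")
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    if np.any(np.abs(succ_r) >= 1):
        raise ValueError("successive correlations must lie in (-1, 1)")
    alleles = np.empty((n, L, 2), dtype=np.int8)
    alleles[:, 0, :] = rng.random((n, 2)) < maf[0]
    for l in range(1, L):
        p_prev, p_cur, r = maf[l - 1], maf[l], succ_r[l - 1]
        q_prev, q_cur = 1 - p_prev, 1 - p_cur
        s = r * np.sqrt(p_cur * q_cur / (p_prev * q_prev))
        p1 = p_cur + s * q_prev  # P(allele=1 | previous allele=1)
        p0 = p_cur - s * p_prev  # P(allele=1 | previous allele=0)
        lo, hi = 0.0, 1.0
        if p1 < lo or p1 > hi or p0 < lo or p0 > hi:
            msg = (
                f"(maf, r) = ({p_cur:.3g}, {r:.3g}) at position {l} is "
                "infeasible for a bivariate Bernoulli; clipping to the "
                "Frechet bound"
            )
            if strict:
                raise InfeasibleConstraintError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            p1, p0 = np.clip(p1, lo, hi), np.clip(p0, lo, hi)
        prob = np.where(alleles[:, l - 1, :] == 1, p1, p0)
        alleles[:, l, :] = rng.random((n, 2)) < prob
    return alleles.sum(axis=2).astype(np.int8)


def random_instrument_matrix(
    L: int,
    K: int,
    strength_range: tuple[float, float] = (0.1, 0.3),
    det_min: float | None = None,
    det_max: float | None = None,
    seed=None,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Rejection-sample an L x K instrument-effect matrix.

    Entries are uniform in ``strength_range``; the determinant constraint
    applies to the K x K causal block (the first K rows).
    """
    rng = _as_rng(seed)
    lo, hi = strength_range
    for _ in range(max_tries):
        A = rng.uniform(lo, hi, size=(L, K))
        if det_min is None and det_max is None:
            return A
        if L >= K:
            d = abs(np.linalg.det(A[:K, :]))
        else:
            d = float(np.sqrt(max(np.linalg.det(A @ A.T), 0.0)))
        if det_min is not None and d <= det_min:
            continue
        if det_max is not None and d >= det_max:
            continue
        return A
    raise InfeasibleConstraintError(
        f"no matrix satisfying the determinant constraint in {max_tries} draws"
    )


def _effects_matrix(cfg: ScenarioConfig, rng: np.random.Generator):
    """Draw the L x K instrument-effect matrix, zeroing non-causal rows."""
    n_causal = cfg.n_causal
    det_min = cfg.det_min
    det_max = cfg.det_max
    if n_causal == cfg.K:
        block = random_instrument_matrix(
            cfg.K, cfg.K, cfg.instrument_strength_range, det_min, det_max, rng
        )
    else:  # under-determined: fewer causal variants than exposures
        block = random_instrument_matrix(
            n_causal, cfg.K, cfg.instrument_strength_range, None, det_max, rng
        )
    A = np.zeros((cfg.L, cfg.K))
    causal = rng.choice(cfg.L, size=n_causal, replace=False)
    A[np.sort(causal), :] = block
    return A


def simulate_dataset(cfg: ScenarioConfig, seed=None) -> DatasetBundle:
    """Draw one dataset from the scenario's structural equations."""
    rng = _as_rng(cfg.seed if seed is None else seed)
    maf, succ = cfg.resolved_ld()
    g = markov_genotypes(maf, succ, cfg.n, rng)
    ez = g - g.mean(axis=0)
    sd = ez.std(axis=0)
    sd[sd == 0] = 1.0
    ez = ez / sd
    A = _effects_matrix(cfg, rng)
    x = ez @ A + rng.normal(0.0, cfg.noise_sd, size=(cfg.n, cfg.K))
    y = x @ cfg.true_effects + rng.normal(0.0, cfg.noise_sd, size=cfg.n)
    return DatasetBundle(
        genotypes=g, exposures=x, outcome=y, truth=cfg, instrument_effects=A
    )


def pleiotropy_scenario(
    cfg: ScenarioConfig, hidden_exposure_effect: float, seed=None
) -> tuple[DatasetBundle, DatasetBundle]:
    """Generate a complete dataset plus a view hiding the first exposure.

    The full model contains all K exposures with the first one's causal
    effect set to ``hidden_exposure_effect``; the returned view drops that
    exposure, emulating horizontal pleiotropy through an unmeasured gene in
    the same locus.
    """
    if cfg.K < 2:
        raise ValueError("pleiotropy scenarios need at least two exposures")
    effects = cfg.true_effects.copy()
    effects[0] = hidden_exposure_effect
    full_cfg = replace(cfg, diagram="pleiotropy_hidden", true_effects=effects)
    full = simulate_dataset(full_cfg, seed=seed)
    view_cfg = replace(
        full_cfg, K=cfg.K - 1, true_effects=effects[1:], n_causal=None
    )
    view = DatasetBundle(
        genotypes=full.genotypes,
        exposures=full.exposures[:, 1:],
        outcome=full.outcome,
        truth=view_cfg,
        instrument_effects=None
        if full.instrument_effects is None
        else full.instrument_effects[:, 1:],
    )
    return full, view


def wishart_perturb_ld(sigma_ref: np.ndarray, df: int, seed=None) -> np.ndarray:
    """Draw a perturbed LD matrix from a Wishart centred on ``sigma_ref``.

    ``W ~ Wishart(df, sigma_ref / df)`` (so ``E[W] = sigma_ref``), rescaled
    to unit diagonal.  Larger ``df`` concentrates the draw around the
    reference.
    """
    rng = _as_rng(seed)
    sigma_ref = np.asarray(sigma_ref, dtype=float)
    L = sigma_ref.shape[0]
    if df < L:
        raise ValueError(f"Wishart degrees of freedom ({df}) must be >= {L}")
    w = scipy.stats.wishart.rvs(df=df, scale=sigma_ref / df, random_state=rng)
    w = np.atleast_2d(w)
    d = np.sqrt(np.diag(w))
    return w / np.outer(d, d)


def two_sample_scenario(
    cfg: ScenarioConfig, seed=None, ld_df_cap: int | None = None
) -> tuple[DatasetBundle, DatasetBundle]:
    """Independent exposure- and outcome-sample datasets for one locus.

    The two cohorts draw their LD matrices from separate Wishart
    distributions centred on the same reference (degrees of freedom tied to
    the cohort sizes, optionally capped at ``ld_df_cap``), then generate
    genotypes, exposures, and outcomes independently with the same
    structural parameters.
    """
    if cfg.n_eqtl is None or cfg.n_gwas is None:
        raise ValueError("two-sample scenarios need n_eqtl and n_gwas")
    rng = _as_rng(cfg.seed if seed is None else seed)
    ref = cfg.target_ld_matrix()
    maf, _ = cfg.resolved_ld()
    A = _effects_matrix(cfg, rng)
    bundles = []
    for n, tag in ((cfg.n_eqtl, "exposure_sample"), (cfg.n_gwas, "outcome_sample")):
        df = int(max(n, cfg.L))
        if ld_df_cap is not None:
            df = min(df, ld_df_cap)
        ld = wishart_perturb_ld(ref, df, rng)
        succ = np.array([ld[i, i + 1] for i in range(cfg.L - 1)])
        bound = np.array(
            [0.99 * feasible_r_bound(maf[i], maf[i + 1]) for i in range(cfg.L - 1)]
        )
        succ = np.clip(succ, -bound, bound)
        g = markov_genotypes(maf, succ, n, rng)
        ez = g - g.mean(axis=0)
        sd = ez.std(axis=0)
        sd[sd == 0] = 1.0
        ez = ez / sd
        x = ez @ A + rng.normal(0.0, cfg.noise_sd, size=(n, cfg.K))
        y = x @ cfg.true_effects + rng.normal(0.0, cfg.noise_sd, size=n)
        bundles.append(
            DatasetBundle(
                genotypes=g, exposures=x, outcome=y,
                truth=replace(cfg, diagram="two_sample"),
                sample_tag=tag, instrument_effects=A,
            )
        )
    return bundles[0], bundles[1]


def combine_two_sample_summary(
    exposure_sample: DatasetBundle,
    outcome_sample: DatasetBundle,
    ld_source: str = "outcome_sample",
    reference_ld: np.ndarray | None = None,
) -> est.SummaryCovariances:
    """Assemble cross-cohort summary covariances for two-sample estimation.

    ``Sigma_EX`` comes from the exposure cohort, ``Sigma_EY`` from the
    outcome cohort, and ``Sigma_EE`` from the outcome cohort's genotypes (or
    a supplied reference matrix, emulating an external LD panel).
    """
    se = exposure_sample.to_summary()
    so = outcome_sample.to_summary()
    if ld_source == "outcome_sample":
        ld = so.sigma_EE
    elif ld_source == "reference":
        if reference_ld is None:
            raise ValueError("ld_source='reference' requires reference_ld")
        ld = np.asarray(reference_ld, dtype=float)
    else:
        raise ValueError("ld_source must be 'outcome_sample' or 'reference'")
    return est.SummaryCovariances(
        sigma_EX=se.sigma_EX,
        sigma_EY=so.sigma_EY,
        sigma_EE=ld,
        n_exposure=exposure_sample.genotypes.shape[0],
        n_outcome=outcome_sample.genotypes.shape[0],
        instrument_ids=se.instrument_ids,
        exposure_ids=se.exposure_ids,
        sigma_XX=se.sigma_XX,
    )


# ---------------------------------------------------------------------------
# replication harness


_ESTIMATORS = {
    "LS": lambda s: est.ls_estimate(s),
    "GMM": lambda s: est.gmm_estimate(s),
}


@dataclass
class ExperimentResult:
    """Estimates across replicates for a set of estimators."""

    config: ScenarioConfig
    estimates: dict[str, np.ndarray]  # tag -> (reps, K)
    pvals: dict[str, np.ndarray]

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        c = self.config.true_effects
        for tag, arr in self.estimates.items():
            pv = self.pvals[tag]
            for k in range(arr.shape[1]):
                ek = arr[:, k]
                bias = float(ek.mean() - c[k])
                sd = float(ek.std(ddof=1)) if arr.shape[0] > 1 else 0.0
                rows.append(
                    {
                        "estimator": tag,
                        "exposure": k,
                        "true_effect": float(c[k]),
                        "mean": float(ek.mean()),
                        "bias": bias,
                        "sd": sd,
                        "rmse": float(np.sqrt(np.mean((ek - c[k]) ** 2))),
                        "reject_rate": float(np.mean(pv[:, k] < alpha)),
                        "reps": arr.shape[0],
                    }
                )
        return pd.DataFrame(rows)


def _rep_seeds(master_seed: int, reps: int):
    return np.random.SeedSequence(master_seed).spawn(reps)


def replicate_experiment(
    cfg: ScenarioConfig,
    estimator_tags: tuple[str, ...] = ("LS", "GMM"),
    reps: int | None = None,
    seed: int | None = None,
) -> ExperimentResult:
    """Run the scenario ``reps`` times and collect per-estimator estimates.

    Per-replicate seeds are spawned deterministically from the master seed,
    so results are reproducible and replicates are independent.
    """
    reps = cfg.reps if reps is None else reps
    master = cfg.seed if seed is None else seed
    unknown = set(estimator_tags) - set(_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimator tag(s): {sorted(unknown)}")
    K = cfg.K
    estimates = {t: np.empty((reps, K)) for t in estimator_tags}
    pvals = {t: np.empty((reps, K)) for t in estimator_tags}
    for i, ss in enumerate(_rep_seeds(master, reps)):
        bundle = simulate_dataset(cfg, seed=np.random.default_rng(ss))
        s = bundle.to_summary()
        for tag in estimator_tags:
            res = _ESTIMATORS[tag](s)
            estimates[tag][i] = res.effects
            pvals[tag][i] = res.p if res.p is not None else np.nan
    return ExperimentResult(config=cfg, estimates=estimates, pvals=pvals)


# ---------------------------------------------------------------------------
# scenario presets (the study conditions of the validation experiments)


def single_instrument_config(
    strength: float = 0.8, effect: float = 0.3, n: int = 10_000,
    reps: int = 1000, seed: int = 0, maf: float = 0.3,
) -> ScenarioConfig:
    """Classical one-instrument, one-exposure diagram (true effect 0.3)."""
    return ScenarioConfig(
        diagram="single_IV", L=1, K=1, true_effects=[effect],
        instrument_strength_range=(strength, strength),
        ld_maf=[maf], n=n, reps=reps, seed=seed,
    )


def two_exposure_config(
    alpha: float = 0.3,
    effects=(0.2, 0.6),
    strength_range=(0.1, 0.3),
    det_min: float | None = 0.05,
    n: int = 10_000,
    reps: int = 1000,
    seed: int = 0,
) -> ScenarioConfig:
    """Two correlated instruments, two exposures (true effects 0.2 and 0.6)."""
    return ScenarioConfig(
        diagram="exact_K", L=2, K=2, true_effects=effects,
        instrument_strength_range=strength_range, ld_alpha=alpha,
        det_min=det_min, n=n, reps=reps, seed=seed,
    )


def underdetermined_config(
    alpha: float = 0.3, effects=(0.2, 0.6), n: int = 10_000,
    reps: int = 200, seed: int = 0,
) -> ScenarioConfig:
    """One causal variant, two exposures: effects are non-identifiable."""
    return ScenarioConfig(
        diagram="underdetermined", L=2, K=2, true_effects=effects,
        n_causal=1, ld_alpha=alpha, n=n, reps=reps, seed=seed,
    )


def feasible_r_bound(maf_a: float, maf_b: float) -> float:
    """Largest positive correlation a bivariate Bernoulli pair can attain.

    Real LD obeys the same Frechet constraint: strongly linked variants must
    have similar allele frequencies.
    """
    pa, qa, pb, qb = maf_a, 1 - maf_a, maf_b, 1 - maf_b
    return float(min(np.sqrt(pa * qb / (qa * pb)), np.sqrt(pb * qa / (qb * pa))))


def _locus_ld(rng: np.random.Generator, L: int):
    maf = rng.uniform(0.1, 0.4, size=L)
    succ = np.empty(L - 1)
    for i in range(L - 1):
        hi = min(0.8, 0.95 * feasible_r_bound(maf[i], maf[i + 1]))
        succ[i] = rng.uniform(0.3, max(hi, 0.3))
    return maf, succ


def three_gene_locus_config(
    L: int = 7,
    effects=(0.15, -0.05, -0.27),
    strength_range=(0.1, 0.3),
    n: int = 10_000,
    reps: int = 1000,
    seed: int = 0,
) -> ScenarioConfig:
    """Overdetermined three-gene locus (modelled on *SLC22A3*-*LPA*-*PLG*).

    Seven instruments by default, of which three randomly chosen variants
    are causal for all three genes; the remaining variants are associated
    with the exposures only through LD.
    """
    maf, succ = _locus_ld(np.random.default_rng(seed + 101), L)
    return ScenarioConfig(
        diagram="overdetermined", L=L, K=3, true_effects=effects,
        instrument_strength_range=strength_range, ld_maf=maf, ld_succ_r=succ,
        n_causal=3, n=n, reps=reps, seed=seed,
    )


def two_gene_locus_config(
    L: int = 5,
    effects=(0.208, -0.294),
    strength_range=(0.1, 0.3),
    n: int = 20_000,
    n_eqtl: int | None = None,
    n_gwas: int | None = None,
    reps: int = 500,
    seed: int = 0,
) -> ScenarioConfig:
    """Two-gene, five-instrument locus (modelled on *MRAS*-*ESYT3*)."""
    maf, succ = _locus_ld(np.random.default_rng(seed + 202), L)
    return ScenarioConfig(
        diagram="two_sample" if n_eqtl else "overdetermined",
        L=L, K=2, true_effects=effects,
        instrument_strength_range=strength_range, ld_maf=maf, ld_succ_r=succ,
        n_causal=2, n=n, n_eqtl=n_eqtl, n_gwas=n_gwas, reps=reps, seed=seed,
    )
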