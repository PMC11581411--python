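"""Finite-sample causal-effect estimators from summary covariances.

All estimators consume the sufficient statistics of an MVMR analysis with
correlated instruments: the instrument-exposure covariance matrix
``Sigma_EX`` (L x K), the instrument-outcome covariance vector ``Sigma_EY``
(L), and the instrument correlation (LD) matrix ``Sigma_EE`` (L x L).

* least squares (``LS``): ``c = (B'B)^-1 B' Sigma_EY`` with ``B = Sigma_EX``
  — the "regression of regression coefficients" estimator;
* weighted GMM: ``c = (B' D B)^-1 B' D Sigma_EY`` for a positive-definite
  weight ``D``;
* GMM with the LD-inverse weight ``D = Sigma_EE^-1`` — the minimum-variance
  member of the family under homoskedastic errors, identical to two-stage
  least squares.

For a square full-rank ``Sigma_EX`` (exactly determined system) all members
of the family coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .sem import UnderdeterminedError

__all__ = [
    "SummaryCovariances",
    "CausalEffectEstimate",
    "DegenerateInputError",
    "covariances_from_samples",
    "ls_estimate",
    "gmm_weighted",
    "gmm_estimate",
    "univariate_ratio",
    "standardized_covariance_from_beta",
]


class DegenerateInputError(ValueError):
    """Raised for inputs that carry no usable signal (constant columns...)."""


@dataclass
class SummaryCovariances:
    """Summary statistics sufficient for all estimators in this module.

    Covariances are on the scale used for estimation: instruments are always
    standardized (so ``sigma_EE`` is the LD correlation matrix); exposures
    and outcome are standardized or merely centered depending on how the
    summaries were built.  ``sigma_XX`` (exposure covariance) is optional and
    only needed for conditional instrument-strength diagnostics.
    """

    sigma_EX: np.ndarray
    sigma_EY: np.ndarray
    sigma_EE: np.ndarray
    n_exposure: int | None = None
    n_outcome: int | None = None
    instrument_ids: list[str] | None = None
    exposure_ids: list[str] | None = None
    sigma_XX: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma_EX = np.atleast_2d(np.asarray(self.sigma_EX, dtype=float))
        if self.sigma_EX.shape[0] == 1 and self.sigma_EX.shape[1] > 1:
            # a 1-D vector passed for a single exposure
            self.sigma_EX = self.sigma_EX.T
        self.sigma_EY = np.asarray(self.sigma_EY, dtype=float).ravel()
        self.sigma_EE = np.atleast_2d(np.asarray(self.sigma_EE, dtype=float))
        L, K = self.sigma_EX.shape
        if L < 1:
            raise ValueError("need at least one instrument")
        if self.sigma_EY.shape != (L,):
            raise ValueError("sigma_EY length does not match instrument count")
        if self.sigma_EE.shape != (L, L):
            raise ValueError("sigma_EE shape does not match instrument count")
        if not np.allclose(self.sigma_EE, self.sigma_EE.T, atol=1e-8):
            raise ValueError("sigma_EE must be symmetric")
        if not np.allclose(np.diag(self.sigma_EE), 1.0, atol=1e-6):
            raise ValueError("sigma_EE must have unit diagonal (correlation scale)")
        if self.instrument_ids is None:
            self.instrument_ids = [f"E{i + 1}" for i in range(L)]
        if self.exposure_ids is None:
            self.exposure_ids = [f"X{j + 1}" for j in range(K)]
        if len(self.instrument_ids) != L or len(self.exposure_ids) != K:
            raise ValueError("id lists do not match matrix dimensions")
        if self.sigma_XX is not None:
            self.sigma_XX = np.atleast_2d(np.asarray(self.sigma_XX, dtype=float))
            if self.sigma_XX.shape != (K, K):
                raise ValueError("sigma_XX shape does not match exposure count")

    @property
    def n_instruments(self) -> int:
        return self.sigma_EX.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.sigma_EX.shape[1]


@dataclass
class CausalEffectEstimate:
    """Per-exposure direct effect estimates with inference and diagnostics.

    Effects are on the scale of the input summaries; for a dichotomous
    outcome analyzed through logistic-regression GWAS betas this is the
    change in log-odds per standard deviation of exposure.
    """

    effects: np.ndarray
    se: np.ndarray | None
    p: np.ndarray | None
    estimator: str
    exposure_ids: list[str]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float).ravel()
        K = self.effects.shape[0]
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float).ravel()
            if self.se.shape != (K,) or np.any(self.se < 0):
                raise ValueError("se must be non-negative with one entry per exposure")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=float).ravel()
            if self.p.shape != (K,) or np.any((self.p < 0) | (self.p > 1)):
                raise ValueError("p must lie in [0, 1] with one entry per exposure")


def covariances_from_samples(
    e: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    scale_phenotypes: bool = True,
    instrument_ids: list[str] | None = None,
    exposure_ids: list[str] | None = None,
) -> SummaryCovariances:
    """Empirical summary covariances from individual-level data.

    Genotype columns are always standardized (mean 0, SD 1, denominator N),
    so ``sigma_EE`` is the empirical LD correlation matrix.  With
    ``scale_phenotypes=True`` (the default, matching how real summary
    statistics are harmonized) exposures and outcome are standardized too;
    with ``False`` they are centered only, leaving effects on the structural
    scale of the data-generating model.
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    if e.shape[0] == 1:
        e = e.T
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = e.shape[0]
    if n < 2:
        raise DegenerateInputError("need at least two observations")
    if x.shape[0] != n or y.shape[0] != n:
        raise ValueError("e, x and y must have the same number of rows")

    def _standardize(m, labels, scale=True):
        m = m - m.mean(axis=0)
        sd = m.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DegenerateInputError(f"constant column(s): {[labels[i] for i in bad]}")
        return m / sd if scale else m

    iid = instrument_ids or [f"E{i + 1}" for i in range(e.shape[1])]
    xid = exposure_ids or [f"X{j + 1}" for j in range(x.shape[1])]
    ez = _standardize(e, iid)
    xz = _standardize(x, xid, scale=scale_phenotypes)
    yz = _standardize(y[:, None], ["Y"], scale=scale_phenotypes).ravel()
    return SummaryCovariances(
        sigma_EX=ez.T @ xz / n,
        sigma_EY=ez.T @ yz / n,
        sigma_EE=ez.T @ ez / n,
        n_exposure=n,
        n_outcome=n,
        instrument_ids=iid,
        exposure_ids=xid,
        sigma_XX=xz.T @ xz / n,
    )


def _check_rank(B: np.ndarray, rank_tol: float = 1e-8) -> dict:
    sv = np.linalg.svd(B, compute_uv=False)
    rank = int(np.sum(sv > rank_tol * sv[0])) if sv[0] > 0 else 0
    gram = B.T @ B
    diag = {
        "singular_values": sv,
        "rank_EX": rank,
        "det_gram_EX": float(np.linalg.det(gram)),
        "cond_EX": float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf,
    }
    if rank < B.shape[1]:
        raise UnderdeterminedError(
            f"rank(Sigma_EX) = {rank} < {B.shape[1]} exposures "
            f"(det of Gram matrix = {diag['det_gram_EX']:.3g}); the system is "
            "under-determined"
        )
    return diag


def _finish(s, c_hat, tag, diag, n=None, delta=None, sigma2=1.0):
    # SEs/p-values attached only when an outcome sample size is known
    from . import inference  # local import to avoid a cycle

    n = n if n is not None else s.n_outcome
    se = p = None
    if n is not None:
        se = inference.se_summary(s, c_hat, n, delta=delta, sigma2=sigma2)
        p = inference.pvalues(c_hat, se)
    return CausalEffectEstimate(
        effects=c_hat, se=se, p=p, estimator=tag,
        exposure_ids=list(s.exposure_ids), diagnostics=diag,
    )


def ls_estimate(s: SummaryCovariances, n: int | None = None) -> CausalEffectEstimate:
    """Least-squares ("regression of regression coefficients") estimator."""
    B = s.sigma_EX
    diag = _check_rank(B)
    c_hat, *_ = np.linalg.lstsq(B, s.sigma_EY, rcond=None)
    return _finish(s, c_hat, "LS", diag, n=n, delta=np.eye(s.n_instruments))


def gmm_weighted(
    s: SummaryCovariances, delta: np.ndarray, n: int | None = None
) -> CausalEffectEstimate:
    """GMM estimator with an explicit positive-definite L x L weight matrix."""
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    L = s.n_instruments
    if delta.shape != (L, L) or not np.allclose(delta, delta.T, atol=1e-8):
        raise ValueError("delta must be a symmetric L x L matrix")
    try:
        R = scipy.linalg.cholesky(delta)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("delta must be positive definite") from exc
    B = s.sigma_EX
    diag = _check_rank(B)
    # solve the weighted normal equations through the Cholesky factor
    RB = R @ B
    Ry = R @ s.sigma_EY
    c_hat, *_ = np.linalg.lstsq(RB, Ry, rcond=None)
    return _finish(s, c_hat, "GMM(Delta)", diag, n=n, delta=delta)


def gmm_estimate(
    s: SummaryCovariances, n: int | None = None, cond_warn: float = 1e8
) -> CausalEffectEstimate:
    """GMM estimator with the LD-inverse weight (two-stage least squares)."""
    G = s.sigma_EE
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "the LD matrix is (near-)singular; prune instruments in perfect LD "
            f"before estimation (condition number {cond:.3g})"
        )
    if cond > cond_warn:
        warnings.warn(
            f"near-singular LD matrix (condition number {cond:.3g}); "
            "estimates may be unstable", RuntimeWarning, stacklevel=2,
        )
    cho = scipy.linalg.cho_factor(G)
    B = s.sigma_EX
    diag = _check_rank(B)
    diag["cond_EE"] = float(cond)
    GiB = scipy.linalg.cho_solve(cho, B)
    Giy = scipy.linalg.cho_solve(cho, s.sigma_EY)
    c_hat = np.linalg.solve(B.T @ GiB, B.T @ Giy)
    est = _finish(s, c_hat, "GMM", diag, n=n, delta=None)
    return est


def univariate_ratio(sigma_EY: float, sigma_EX: float) -> float:
    """Classical instrumental-variable ratio ``c = sigma_EY / sigma_EX``."""
    if sigma_EX == 0:
        raise DegenerateInputError(
            "null instrument: the instrument-exposure covariance is zero"
        )
    return float(sigma_EY) / float(sigma_EX)


def standardized_covariance_from_beta(
    beta: np.ndarray, maf: np.ndarray, trait_sd: float | np.ndarray = 1.0
) -> np.ndarray:
    """Convert per-allele regression betas to standardized-scale covariances.

    Under Hardy-Weinberg equilibrium the genotype SD is
    ``sqrt(2 maf (1 - maf))``, and the covariance between the standardized
    genotype and the trait is ``beta * SD(genotype) / SD(trait)``.
    """
    beta = np.asarray(beta, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("minor allele frequencies must lie in (0, 1)")
    snp_sd = np.sqrt(2.0 * maf * (1.0 - maf))
    return beta * snp_sd / trait_sd
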