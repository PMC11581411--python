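"""Standard errors, p-values, multiple testing, and instrument diagnostics.

Inference for the GMM family follows the usual sandwich form.  For the
estimator ``c = (B' D B)^-1 B' D Sigma_EY`` with weight ``D`` and
``B = Sigma_EX``, the asymptotic covariance under homoskedastic outcome
errors with variance ``sigma^2`` is

    Var(c) = sigma^2 / n * (B'DB)^-1 B' D Sigma_EE D B (B'DB)^-1,

which for the LD-inverse weight collapses to
``sigma^2 / n * (B' Sigma_EE^-1 B)^-1``.  By default ``sigma^2 = 1``
(outcome on unit-variance scale), a deliberately conservative choice; pass
``sigma2`` explicitly to subtract explained variance.

Instrument strength is assessed by conditional F-statistics in the style of
Sanderson and Windmeijer: the strength of each exposure's instruments after
projecting out the genetically predicted values of the remaining exposures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

from .estimators import SummaryCovariances

__all__ = [
    "DiagnosticsReport",
    "se_summary",
    "se_individual",
    "pvalues",
    "bonferroni_threshold",
    "conditional_f",
    "determinacy_check",
]


@dataclass
class DiagnosticsReport:
    """Determinant/rank/strength diagnostics for one instrument-exposure set."""

    det_EE: float
    det_A_proxy: float
    rank_EX: int
    cond_EE: float
    cond_F: np.ndarray | None
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "det_EE": self.det_EE,
            "det_A_proxy": self.det_A_proxy,
            "rank_EX": self.rank_EX,
            "cond_EE": self.cond_EE,
            "cond_F": None if self.cond_F is None else list(map(float, self.cond_F)),
            "flags": sorted(self.flags),
        }


def _sandwich_cov(s: SummaryCovariances, delta: np.ndarray | None) -> np.ndarray:
    B = s.sigma_EX
    G = s.sigma_EE
    if delta is None:  # LD-inverse weight: (B' G^-1 B)^-1
        cho = scipy.linalg.cho_factor(G)
        M = B.T @ scipy.linalg.cho_solve(cho, B)
        return np.linalg.inv(M)
    H = np.linalg.inv(B.T @ delta @ B)
    return H @ (B.T @ delta @ G @ delta @ B) @ H


def se_summary(
    s: SummaryCovariances,
    c_hat: np.ndarray,
    n: int,
    delta: np.ndarray | None = None,
    sigma2: float = 1.0,
) -> np.ndarray:
    """Summary-data standard errors from the asymptotic sandwich covariance.

    ``delta`` is the weight matrix of the estimator the SEs belong to
    (``None`` means the LD-inverse GMM weight).  ``n`` is the outcome-sample
    size, the only sample size available in a two-sample summary analysis;
    extra two-sample variability is not modelled.
    """
    c_hat = np.asarray(c_hat, dtype=float).ravel()
    K = s.n_exposures
    if n is None or n <= K:
        raise ValueError(f"sample size n={n} must exceed the number of exposures {K}")
    if s.n_exposure is not None and s.n_outcome is not None:
        if s.n_exposure != s.n_outcome:
            warnings.warn(
                "two-sample summary data: standard errors ignore variability "
                "from the exposure-sample size",
                RuntimeWarning,
                stacklevel=2,
            )
    cov = _sandwich_cov(s, delta) * (max(sigma2, 0.0) / n)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def se_individual(
    e: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    c_hat: np.ndarray,
    scale_phenotypes: bool = False,
) -> np.ndarray:
    """Classical homoskedastic two-stage least-squares standard errors.

    Computed from individual-level (one-sample) data: residual variance of
    ``y - x c_hat`` combined with the Gram matrix of the first-stage fitted
    exposures.
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    if e.shape[0] == 1:
        e = e.T
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float).ravel()
    c_hat = np.asarray(c_hat, dtype=float).ravel()
    n, K = x.shape
    if n <= K:
        raise ValueError(f"sample size n={n} must exceed the number of exposures {K}")

    def _prep(m, scale):
        m = m - m.mean(axis=0)
        return m / m.std(axis=0) if scale else m

    ez = _prep(e, True)
    xz = _prep(x, scale_phenotypes)
    yz = _prep(y[:, None], scale_phenotypes).ravel()
    resid = yz - xz @ c_hat
    dof = max(n - K, 1)
    sigma2 = float(resid @ resid) / dof
    # first-stage projection of exposures onto the instrument span
    coef, *_ = np.linalg.lstsq(ez, xz, rcond=None)
    xhat = ez @ coef
    cov = np.linalg.inv(xhat.T @ xhat) * sigma2
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def pvalues(c_hat: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values for the null of zero causal effect."""
    c_hat = np.asarray(c_hat, dtype=float).ravel()
    se = np.asarray(se, dtype=float).ravel()
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    p = np.ones_like(c_hat)
    ok = se > 0
    p[ok] = 2.0 * scipy.stats.norm.sf(np.abs(c_hat[ok]) / se[ok])
    degenerate = (~ok) & (c_hat != 0)
    if np.any(degenerate):
        warnings.warn(
            "zero standard error with nonzero estimate; reporting p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        p[degenerate] = 0.0
    return p


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise significance threshold ``alpha / m_tests``."""
    if alpha <= 0 or m_tests < 1:
        raise ValueError("alpha must be positive and m_tests at least 1")
    return alpha / m_tests


def _first_stage_quantities(s: SummaryCovariances):
    if s.sigma_XX is None:
        warnings.warn(
            "exposure covariance matrix unavailable; assuming unit exposure "
            "variances for conditional F-statistics",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.eye(s.n_exposures)
    return s.sigma_XX


def conditional_f(s: SummaryCovariances, n: int) -> np.ndarray:
    """Conditional F-statistics for instrument strength per exposure.

    For each exposure k, the remaining exposures are regressed out using
    their instrument-predicted values (a two-stage regression of exposure k
    on the others), and the F-statistic of the instruments in the regression
    of that residual is returned.  With a single exposure this reduces to
    the ordinary first-stage F-statistic.
    """
    L, K = s.n_instruments, s.n_exposures
    if n <= L + 1:
        raise ValueError("sample size too small for the F denominator")
    G = s.sigma_EE
    B = s.sigma_EX
    XX = _first_stage_quantities(s)
    cho = scipy.linalg.cho_factor(G)
    GiB = scipy.linalg.cho_solve(cho, B)

    if K == 1:
        r2 = float(B[:, 0] @ GiB[:, 0]) / float(XX[0, 0])
        q, dof = L, n - L - 1
        f = (r2 / q) / max((1.0 - r2) / dof, np.finfo(float).tiny)
        return np.array([max(f, 0.0)])

    out = np.empty(K)
    for k in range(K):
        others = [j for j in range(K) if j != k]
        Bk = B[:, k]
        Bo = B[:, others]
        Gio = GiB[:, others]
        M = Bo.T @ Gio
        try:
            delta = np.linalg.solve(M, Bo.T @ GiB[:, k])
        except np.linalg.LinAlgError:
            out[k] = 0.0
            continue
        sigma_Er = Bk - Bo @ delta
        ess = float(sigma_Er @ scipy.linalg.cho_solve(cho, sigma_Er))
        sigma_rr = float(
            XX[k, k]
            - 2.0 * delta @ XX[np.ix_(others, [k])].ravel()
            + delta @ XX[np.ix_(others, others)] @ delta
        )
        rss = sigma_rr - ess
        q = L - (K - 1)
        dof = n - L - 1
        if sigma_rr <= 1e-12 or rss <= 1e-12:
            # no independent variation left (e.g. duplicated exposures)
            out[k] = 0.0 if ess <= 1e-12 else np.inf
            continue
        out[k] = max((ess / q) / (rss / dof), 0.0)
    return out


def determinacy_check(
    s: SummaryCovariances,
    n: int | None = None,
    rank_rel_tol: float = 1e-8,
    weak_det_threshold: float = 1e-3,
    cond_warn: float = 1e8,
) -> DiagnosticsReport:
    """Report rank/determinant diagnostics and flag problem configurations.

    ``under_determined`` is raised when the instrument-exposure covariance is
    rank deficient — exactly (relative singular-value tolerance) or, when a
    sample size is supplied, statistically: the smallest singular value is
    compared with the sampling-noise floor ``2 (sqrt(L) + sqrt(K)) / sqrt(n)``
    expected for a rank-deficient population matrix.  ``weak_instruments``
    flags a determinant proxy below ``weak_det_threshold``;
    ``near_singular_LD`` flags an ill-conditioned LD matrix.
    """
    B = s.sigma_EX
    G = s.sigma_EE
    L, K = B.shape
    sv = np.linalg.svd(B, compute_uv=False)
    rank = int(np.sum(sv > rank_rel_tol * sv[0])) if sv[0] > 0 else 0
    if L == K:
        det_proxy = float(np.linalg.det(B))
    else:
        gram_det = float(np.linalg.det(B.T @ B))
        det_proxy = float(np.sqrt(max(gram_det, 0.0)))
    det_EE = float(np.linalg.det(G))
    cond_EE = float(np.linalg.cond(G))

    flags: set[str] = set()
    if rank < K:
        flags.add("under_determined")
    if n is not None:
        noise_floor = 2.0 * (np.sqrt(L) + np.sqrt(K)) / np.sqrt(n)
        if sv[-1] < noise_floor:
            flags.add("under_determined")
    if abs(det_proxy) < weak_det_threshold:
        flags.add("weak_instruments")
    if cond_EE > cond_warn or det_EE < 1e-12:
        flags.add("near_singular_LD")

    cond_F = None
    if (
        n is not None and n > L + 1 and s.sigma_XX is not None
        and "under_determined" not in flags
    ):
        try:
            cond_F = conditional_f(s, n)
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            cond_F = None
    return DiagnosticsReport(
        det_EE=det_EE,
        det_A_proxy=det_proxy,
        rank_EX=rank,
        cond_EE=cond_EE,
        cond_F=cond_F,
        flags=flags,
    )
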