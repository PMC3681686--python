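"""Variance components, GLS effect estimates, and effect decorrelation.

The stacked model for one probe/SNP pair is

    y = X a + Z b + u + e,      u ~ N(0, sigma_g2 * K),   e ~ N(0, sigma_e2 * I)

where X holds tissue intercepts, Z holds tissue-specific dosage columns, and
K is the 0/1 individual-sharing matrix.  The two variance components are
estimated by maximum likelihood after a one-time spectral decomposition of K:
writing V = sigma_e2 * (delta * K + I) with ratio delta = sigma_g2 / sigma_e2,
the likelihood profiles analytically over the fixed effects and sigma_e2,
leaving a one-dimensional search over delta (a log-spaced grid refined by
bounded scalar minimization).  Per-tissue SNP effects and their covariance
then come from generalized least squares under the fitted V.

Because tissues share individuals the per-tissue effect estimates are
correlated.  `decorrelate` converts the covariance matrix into per-tissue
"un-correlated" variances Lambda_i = 1 / (Sigma^-1 1)_i such that standard
independent-inputs inverse-variance meta-analysis on (beta, Lambda) reproduces
the optimal correlated statistic 1' Sigma^-1 beta / sqrt(1' Sigma^-1 1).

`marginal_error_correction` addresses two practical mismatches between the
joint fit and single-tissue regression: effect estimates are t-distributed
(not normal), and the joint fit pools the residual error across tissues.  It
rescales each tissue's standard error so that the marginal z-score equals the
normal-quantile-matched version of that tissue's own t statistic, preserving
the estimated correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "VarianceComponents",
    "EffectEstimates",
    "SpectralKernel",
    "estimate_variance_components",
    "gls_effects",
    "decorrelate",
    "t_statistic_to_z",
    "marginal_error_correction",
]

#: delta = sigma_g2/sigma_e2 search grid (log10 bounds, number of points)
DELTA_LOG10_LO = -5.0
DELTA_LOG10_HI = 5.0
DELTA_GRID_SIZE = 100
#: convergence tolerance of the bounded refinement over log10(delta)
DELTA_XATOL = 1e-8


@dataclass(frozen=True)
class VarianceComponents:
    """ML estimates of the sharing and residual variance coefficients."""

    sigma_g2: float
    sigma_e2: float
    loglik: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0:
            raise ValueError("sigma_g2 must be nonnegative")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")
        if not np.isfinite(self.loglik):
            raise ValueError("non-finite log-likelihood")

    def covariance(self, K: np.ndarray) -> np.ndarray:
        """V = sigma_g2 * K + sigma_e2 * I."""
        n = K.shape[0]
        return self.sigma_g2 * np.asarray(K, dtype=float) + self.sigma_e2 * np.eye(n)


@dataclass
class EffectEstimates:
    """Per-tissue SNP effects with covariance and (optionally) decorrelated se.

    ``se`` holds plain marginal standard errors (sqrt of the covariance
    diagonal) until :func:`decorrelate` replaces them with the un-correlated
    construction and flips ``decorrelated``.
    """

    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    decorrelated: bool = False
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        self.se = np.atleast_1d(np.asarray(self.se, dtype=float))
        k = self.beta.shape[0]
        if self.cov.shape != (k, k) or self.se.shape != (k,):
            raise ValueError("beta, cov and se dimensions disagree")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be strictly positive")

    @property
    def n_tissues(self) -> int:
        return self.beta.shape[0]


class SpectralKernel:
    """One-time eigendecomposition of a sharing matrix K.

    Reused across probes and SNPs for the same tissue layout: every
    likelihood evaluation and GLS solve happens in the rotated basis where K
    is diagonal, so each costs O(n * p) instead of O(n^3).
    """

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(K, K.T):
            raise ValueError("K must be symmetric")
        if not np.allclose(np.diag(K), 1.0):
            raise ValueError("K must have unit diagonal")
        eigenvalues, U = np.linalg.eigh(K)
        # K = M M^T is PSD; clip tiny negative round-off
        self.eigenvalues = np.clip(eigenvalues, 0.0, None)
        self.U = U
        self.n = K.shape[0]

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.U.T @ a


def _profile_loglik_grid(
    yt: np.ndarray, Xt: np.ndarray, lam: np.ndarray, deltas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Profile log-likelihood at each delta (vectorized over the grid).

    Returns (loglik per delta, sigma_e2 per delta).  Fixed effects and
    sigma_e2 are profiled out analytically at each delta.
    """
    n, p = Xt.shape
    d = deltas[:, None] * lam[None, :] + 1.0  # (G, n)
    w = 1.0 / d
    A = np.einsum("ni,gn,nj->gij", Xt, w, Xt)  # (G, p, p)
    b = np.einsum("ni,gn,n->gi", Xt, w, yt)  # (G, p)
    try:
        beta = np.linalg.solve(A, b[..., None])[..., 0]  # (G, p)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient fixed-effect matrix") from exc
    resid = yt[None, :] - beta @ Xt.T  # (G, n)
    rss = np.einsum("gn,gn->g", resid * w, resid)
    sigma_e2 = rss / n
    loglik = -0.5 * (
        n * np.log(2.0 * np.pi * sigma_e2) + np.log(d).sum(axis=1) + n
    )
    return loglik, sigma_e2


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    *,
    kernel: SpectralKernel | None = None,
) -> VarianceComponents:
    """ML fit of (sigma_g2, sigma_e2) for y ~ N(X b, sigma_g2 K + sigma_e2 I).

    Either the sharing matrix ``K`` or a precomputed :class:`SpectralKernel`
    must be given.  The variance ratio delta = sigma_g2/sigma_e2 is searched
    on a 100-point log grid over [1e-5, 1e5], refined by bounded scalar
    minimization; the boundary delta = 0 (no sharing variance) is always
    evaluated and wins ties, so sigma_g2 = 0 is returned exactly when the
    likelihood prefers the boundary.
    """
    if kernel is None:
        if K is None:
            raise ValueError("either K or a SpectralKernel is required")
        kernel = SpectralKernel(K)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != kernel.n or y.shape[0] != kernel.n:
        raise ValueError("y, X and K dimensions disagree")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect matrix X is rank deficient")

    yt = kernel.rotate(y)
    Xt = kernel.rotate(X)
    lam = kernel.eigenvalues

    log_deltas = np.linspace(DELTA_LOG10_LO, DELTA_LOG10_HI, DELTA_GRID_SIZE)
    deltas = np.concatenate([[0.0], 10.0**log_deltas])
    ll, sig = _profile_loglik_grid(yt, Xt, lam, deltas)
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite likelihood encountered on the delta grid")
    best = int(np.argmax(ll))

    best_delta, best_ll, best_sig = deltas[best], ll[best], sig[best]
    if best > 0:
        # refine around the best grid point (in log10 space)
        lo = log_deltas[max(best - 2, 0)]
        hi = log_deltas[min(best, DELTA_GRID_SIZE - 1)]

        def neg_profile(ld: float) -> float:
            l, _ = _profile_loglik_grid(yt, Xt, lam, np.array([10.0**ld]))
            return -l[0]

        res = optimize.minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": DELTA_XATOL, "maxiter": 100},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_delta = 10.0**res.x
            l, s = _profile_loglik_grid(yt, Xt, lam, np.array([best_delta]))
            best_ll, best_sig = l[0], s[0]

    return VarianceComponents(
        sigma_g2=float(best_delta * best_sig),
        sigma_e2=float(best_sig),
        loglik=float(best_ll),
    )


def gls_effects(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    *,
    n_snp: int | None = None,
) -> EffectEstimates:
    """Generalized least squares under covariance V.

    ``X`` is the full fixed-effect matrix ``[intercept_block | snp_block]``;
    the trailing ``n_snp`` columns (default: the second half) are the
    per-tissue SNP effects.  Returns their estimates and the matching block of
    ``(X' V^-1 X)^-1``; intercepts ride along for diagnostics.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.asarray(V, dtype=float)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("V must be positive definite") from exc
    # whiten: solve L z = x  =>  z' z = x' V^-1 x
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    A = Xw.T @ Xw
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("X' V^-1 X is singular") from exc
    full_beta = A_inv @ (Xw.T @ yw)
    p = X.shape[1]
    if n_snp is None:
        if p % 2:
            raise ValueError("cannot infer the SNP block; pass n_snp explicitly")
        n_snp = p // 2
    snp = slice(p - n_snp, p)
    cov = A_inv[snp, snp]
    return EffectEstimates(
        beta=full_beta[snp],
        cov=cov,
        se=np.sqrt(np.diag(cov)),
        decorrelated=False,
        intercepts=full_beta[: p - n_snp],
    )


def decorrelate(est: EffectEstimates) -> EffectEstimates:
    """Replace correlated covariance with "un-correlated" per-tissue variances.

    Lambda_i = 1 / (Sigma^-1 1)_i, so that inverse-variance weighting with
    weights 1/Lambda_i reproduces both the numerator 1' Sigma^-1 beta and the
    precision 1' Sigma^-1 1 of the optimal correlated fixed-effects statistic.
    For a diagonal Sigma this returns the ordinary variances.  Raises if some
    inverse row sum is non-positive (possible for covariances outside the
    positively-correlated sampling regime), since no positive variance can
    then represent that tissue's weight.
    """
    if est.decorrelated:
        return est
    sigma = est.cov
    try:
        weights = np.linalg.solve(sigma, np.ones(est.n_tissues))
    except np.linalg.LinAlgError as exc:
        raise ValueError("effect covariance must be positive definite") from exc
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] <= 0:
        raise ValueError("effect covariance must be positive definite")
    if np.any(weights <= 0):
        raise ValueError(
            "un-correlated variances are undefined: some inverse row sums of "
            "the effect covariance are non-positive"
        )
    lam = 1.0 / weights
    return EffectEstimates(
        beta=est.beta.copy(),
        cov=sigma.copy(),
        se=np.sqrt(lam),
        decorrelated=True,
        intercepts=None if est.intercepts is None else est.intercepts.copy(),
    )


def t_statistic_to_z(t_stat: float, df: float) -> float:
    """Normal z with the same tail probability as a t statistic with df dof.

    Sign preserved; t = 0 maps to z = 0 for any df; df = inf is the identity.
    """
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if np.isinf(df):
        return float(t_stat)
    if t_stat == 0.0:
        return 0.0
    # work on the |t| tail for numerical stability far out
    tail = stats.t.sf(abs(t_stat), df)
    z = stats.norm.isf(tail)
    return float(np.sign(t_stat) * z)


def marginal_error_correction(
    est: EffectEstimates,
    per_tissue_fits: Sequence,
) -> EffectEstimates:
    """Rescale standard errors to match single-tissue t-based evidence.

    ``per_tissue_fits`` supplies each tissue's single-tissue fit as objects
    with ``t_stat`` and ``df`` attributes (e.g. :class:`eqtlmeta.tbt.TissueFit`)
    or plain ``(beta, se, df)`` triples.  Each tissue's se becomes
    ``|beta_i / z_i|`` with z_i the quantile-matched normal version of the
    tissue's t statistic; the covariance is rebuilt around the new diagonal
    with the original correlation matrix.  Must run before decorrelation.
    """
    if est.decorrelated:
        raise ValueError("apply the error correction before decorrelation")
    k = est.n_tissues
    if len(per_tissue_fits) != k:
        raise ValueError("one single-tissue fit per tissue is required")
    new_se = est.se.copy()
    for i, fit in enumerate(per_tissue_fits):
        if hasattr(fit, "t_stat"):
            t_stat, df = fit.t_stat, fit.df
        else:
            b_i, se_i, df = fit
            t_stat = b_i / se_i
        if df < 1:
            raise ValueError(f"tissue {i}: df must be >= 1")
        z = t_statistic_to_z(t_stat, df)
        if abs(z) > 1e-12 and abs(est.beta[i]) > 0:
            new_se[i] = abs(est.beta[i] / z)
        else:
            # no evidence either way: inflate by the t-vs-normal density ratio
            # at the origin, the small-t limit of |t/z|
            if np.isfinite(df):
                new_se[i] = est.se[i] * stats.norm.pdf(0.0) / stats.t.pdf(0.0, df)
    sd_old = np.sqrt(np.diag(est.cov))
    corr = est.cov / np.outer(sd_old, sd_old)
    new_cov = corr * np.outer(new_se, new_se)
    return EffectEstimates(
        beta=est.beta.copy(),
        cov=new_cov,
        se=new_se,
        decorrelated=False,
        intercepts=None if est.intercepts is None else est.intercepts.copy(),
    )
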