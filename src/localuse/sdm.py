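"""Maximum-likelihood spatial Durbin model and LeSage–Pace impacts.

The model is

    y = rho W y + X beta + W X theta + eps,   eps ~ N(0, sigma^2 I)

with W a row-standardized spatial weights matrix.  Estimation maximizes
the concentrated Gaussian log-likelihood in rho: for each candidate rho,
(beta, theta) solve the least-squares regression of y - rho W y on
[1, X, WX], and

    ell_p(rho) = ln|I - rho W| - (n/2) ln(RSS(rho)/n) + const.

The log-determinant uses the precomputed eigenvalues of W, summing log
moduli so that asymmetric (complex-spectrum) kNN weights are handled.

Because covariate effects feed back through the spatial multiplier
(I - rho W)^{-1}, coefficients are summarized as *impacts*: for IV k with
S_k(W) = (I - rho W)^{-1} (I beta_k + W theta_k), the direct impact is
the mean diagonal of S_k, the total impact the mean row sum, and the
indirect impact their difference.  A dense oracle and a trace-based Monte
Carlo estimator (for interval estimation) are both provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .weights import SpatialWeights

__all__ = ["SDMFit", "ImpactDraws", "fit_sdm", "log_det", "impacts_dense", "impacts_mc"]

logger = logging.getLogger(__name__)

_RHO_EPS = 1e-6  # margin inside the feasible interval
_BOUNDARY_TOL = 1e-5


@dataclass
class SDMFit:
    """Estimated spatial Durbin model.

    ``beta`` includes the intercept (first entry); ``theta`` are the
    lag coefficients for the non-constant IVs.  ``vcov`` covers the
    stacked parameter vector (beta, theta, rho) in that order, from the
    numeric Hessian of the sigma^2-concentrated log-likelihood.
    """

    rho: float
    beta: np.ndarray
    theta: np.ndarray
    sigma2: float
    vcov: np.ndarray
    loglik: float
    residuals: np.ndarray
    iv_names: tuple
    rho_interval: tuple

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.theta, [self.rho]])


@dataclass
class ImpactDraws:
    """Monte Carlo draws of direct/indirect/total impacts per IV.

    Arrays have shape (n_draws, n_ivs); total = direct + indirect
    elementwise by construction.
    """

    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    iv_names: tuple

    @property
    def n_draws(self) -> int:
        return self.direct.shape[0]


def log_det(rho: float, W: SpatialWeights) -> float:
    """ln|I - rho W| from the (cached) eigenvalues of W.

    For complex eigenvalues of asymmetric W the conjugate pairs
    contribute the log of the modulus of their product, i.e. the sum of
    log moduli of the individual factors.
    """
    eigs = W.eigenvalues()
    factors = 1.0 - rho * eigs
    real = np.abs(eigs.imag) < 1e-8
    if np.any(factors[real].real <= 0):
        raise ValueError(f"rho={rho} infeasible: 1 - rho*lambda <= 0 for real lambda")
    return float(np.sum(np.log(np.abs(factors))))


def _design(y, X, W):
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    WX = W.matrix @ X
    Z = np.column_stack([np.ones(n), X, WX])
    return y, X, WX, Z


def _check_collinear(Z, iv_names):
    cols = ["intercept", *iv_names, *[f"lag_{v}" for v in iv_names]]
    _, R = np.linalg.qr(Z)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * diag.max()
    if bad.any():
        names = [cols[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"collinear design columns: {names}")


def fit_sdm(y, X, W: SpatialWeights, iv_names=None) -> SDMFit:
    """Fit the spatial Durbin model by concentrated maximum likelihood.

    Parameters
    ----------
    y : (n,) vector
        Dependent variable (log10 local use in the pipeline).
    X : (n, p) matrix
        Independent variables, without a constant column.
    W : SpatialWeights
        Row-standardized weights; its eigenvalues are computed once and
        cached, so repeated fits on the same W (as in the bootstrap) are
        cheap.
    iv_names : sequence of str, optional
        Names for reporting; defaults to x1..xp.
    """
    y, X, WX, Z = _design(y, X, W)
    n, p = X.shape
    if iv_names is None:
        iv_names = tuple(f"x{j + 1}" for j in range(p))
    iv_names = tuple(iv_names)
    if n <= 2 * p + 2:
        raise ValueError(f"n={n} too small for p={p} IVs (need n > 2p + 2)")
    _check_collinear(Z, iv_names)

    Wy = W.matrix @ y
    # residual-maker applied once: RSS(rho) is quadratic in rho
    coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    coef_Wy, *_ = np.linalg.lstsq(Z, Wy, rcond=None)
    e0 = y - Z @ coef_y
    ed = Wy - Z @ coef_Wy
    a, b, c = e0 @ e0, e0 @ ed, ed @ ed

    lo, hi = W.rho_interval()
    lo, hi = lo + _RHO_EPS, hi - _RHO_EPS

    def neg_profile(rho):
        rss = a - 2 * b * rho + c * rho * rho
        return -(log_det(rho, W) - 0.5 * n * np.log(rss / n))

    res = minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    rho = float(res.x)
    if min(rho - lo, hi - rho) < _BOUNDARY_TOL:
        raise RuntimeError(
            f"rho estimate {rho:.6f} at the boundary of the feasible "
            f"interval ({lo:.4f}, {hi:.4f}); model likely misspecified"
        )

    delta, *_ = np.linalg.lstsq(Z, y - rho * Wy, rcond=None)
    resid = y - rho * Wy - Z @ delta
    rss = float(resid @ resid)
    sigma2 = rss / n
    const = -0.5 * n * (1.0 + np.log(2.0 * np.pi))
    loglik = log_det(rho, W) - 0.5 * n * np.log(sigma2) + const

    vcov = _numeric_vcov(y, Wy, Z, W, np.concatenate([delta, [rho]]), (lo, hi))
    beta = delta[: p + 1]
    theta = delta[p + 1 :]
    return SDMFit(
        rho=rho,
        beta=beta,
        theta=theta,
        sigma2=sigma2,
        vcov=vcov,
        loglik=float(loglik),
        residuals=resid,
        iv_names=iv_names,
        rho_interval=(lo, hi),
    )


def _concentrated_loglik(params, y, Wy, Z, W, n):
    delta, rho = params[:-1], params[-1]
    resid = y - rho * Wy - Z @ delta
    rss = resid @ resid
    return (
        log_det(rho, W)
        - 0.5 * n * np.log(rss / n)
        - 0.5 * n * (1.0 + np.log(2.0 * np.pi))
    )


def _numeric_vcov(y, Wy, Z, W, params, interval, rel_step=1e-5):
    """Central-difference Hessian of the concentrated log-likelihood,
    inverted (negated) to the parameter covariance over (beta, theta, rho)."""
    n = y.size
    d = params.size
    h = rel_step * np.maximum(1.0, np.abs(params))
    # keep rho perturbations inside the feasible interval
    lo, hi = interval
    h[-1] = min(h[-1], 0.49 * (hi - params[-1]), 0.49 * (params[-1] - lo))

    def f(p):
        return _concentrated_loglik(p, y, Wy, Z, W, n)

    H = np.empty((d, d))
    f0 = f(params)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(params + ei) - 2 * f0 + f(params - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(params + ei + ej)
                - f(params + ei - ej)
                - f(params - ei + ej)
                + f(params - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian; using pseudo-inverse for vcov")
        vcov = np.linalg.pinv(-H)
    return 0.5 * (vcov + vcov.T)


def impacts_dense(fit: SDMFit, W: SpatialWeights) -> dict:
    """Exact impacts via the dense spatial multiplier (small-n oracle).

    For each IV k, S_k = (I - rho W)^{-1} (I beta_k + W theta_k);
    direct = mean diagonal, total = mean row sum, indirect = difference.
    For row-standardized W the total reduces to
    (beta_k + theta_k) / (1 - rho) exactly.
    """
    n = W.n
    Wd = W.matrix.toarray()
    A = np.linalg.solve(np.eye(n) - fit.rho * Wd, np.eye(n))
    out = {}
    for k, name in enumerate(fit.iv_names):
        bk, tk = fit.beta[k + 1], fit.theta[k]
        S = bk * A + tk * (A @ Wd)
        direct = float(np.trace(S) / n)
        total = float(S.sum() / n)
        out[name] = {"direct": direct, "indirect": total - direct, "total": total}
    return out


def _nearest_psd(M):
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def impacts_mc(
    fit: SDMFit,
    W: SpatialWeights,
    n_draws: int = 100,
    rng=None,
    q: int = 30,
) -> ImpactDraws:
    """Monte Carlo impact draws using traces of powers of W.

    Draws (beta, theta, rho) from N(estimates, vcov); rho draws outside
    the feasible interval are redrawn (at most 1000 attempts).  For each
    draw the direct impact uses the truncated power series

        direct_k = n^{-1} sum_{j=0}^{q} rho^j (beta_k tr(W^j)
                                               + theta_k tr(W^{j+1}))

    and the total impact the row-standardized closed form
    (beta_k + theta_k)/(1 - rho).  Traces tr(W^j) are precomputed and
    cached on W.
    """
    if rng is None:
        rng = np.random.default_rng()
    mean = fit.params
    vcov = fit.vcov
    eigvals = np.linalg.eigvalsh(0.5 * (vcov + vcov.T))
    if eigvals.min() < -1e-10 * max(1.0, abs(eigvals.max())):
        logger.warning("vcov not positive semidefinite; projecting to nearest PSD")
        vcov = _nearest_psd(vcov)

    if np.allclose(vcov, 0):
        draws = np.tile(mean, (n_draws, 1))
    else:
        # rejection step keeps rho inside its feasible interval
        lo, hi = fit.rho_interval
        draws = np.empty((n_draws, mean.size))
        filled = 0
        for _ in range(1000):
            need = n_draws - filled
            if need == 0:
                break
            cand = rng.multivariate_normal(mean, vcov, size=need, method="svd")
            ok = (cand[:, -1] > lo) & (cand[:, -1] < hi)
            kept = cand[ok]
            draws[filled : filled + len(kept)] = kept
            filled += len(kept)
        else:
            raise RuntimeError("could not draw feasible rho in 1000 attempts")

    p = len(fit.iv_names)
    beta = draws[:, 1 : p + 1]  # (n_draws, p), intercept dropped
    theta = draws[:, p + 1 : 2 * p + 1]
    rho = draws[:, -1]

    traces = W.power_traces(q + 1)  # tr(W^0) .. tr(W^{q+1})
    n = W.n
    rho_pow = rho[:, None] ** np.arange(q + 1)  # (n_draws, q+1)
    g_beta = rho_pow @ traces[: q + 1] / n  # sum_j rho^j tr(W^j)/n
    g_theta = rho_pow @ traces[1 : q + 2] / n  # sum_j rho^j tr(W^{j+1})/n
    direct = beta * g_beta[:, None] + theta * g_theta[:, None]
    total = (beta + theta) / (1.0 - rho)[:, None]
    return ImpactDraws(
        direct=direct, indirect=total - direct, total=total, iv_names=fit.iv_names
    )
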