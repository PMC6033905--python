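"""REML fitter for the day/site crossed linear mixed model.

The PM2.5 calibration model is

    PM_ij = (alpha + u_j) + (beta + v_j) * AOD_ij + s_i + eps_ij

with day-specific random intercept and slope (u_j, v_j) ~ N(0, Sigma)
(correlated, 2x2 covariance), site random intercepts s_i ~ N(0, sigma_s^2)
crossed with days, and residuals eps_ij ~ N(0, sigma^2).  The day effects
absorb day-to-day changes in the AOD-PM relationship (boundary-layer
height, humidity, aerosol type); the site intercepts absorb persistent
local offsets.

Because the two random factors are crossed, the model does not reduce to
a single-grouping-factor mixed model; the restricted likelihood is
maximised directly.  The marginal covariance is

    V = sigma^2 * (I + Z W W' Z')

where Z stacks the day intercept/slope and site indicator columns and W
is the block-diagonal *relative* covariance factor (a 2x2 Cholesky
factor Lambda repeated per day, and a scalar g_s per site), following the
standard relative-covariance parameterisation.  With q = 2*J + I random
effects, all REML quantities are computed through the q x q capacitance
matrix M = I + A'A (A = Z W), so each objective evaluation costs
O(n q + q^3) and the residual variance is profiled out analytically.
Optimisation over the free elements of (Lambda, g_s) is derivative-free
(Nelder-Mead) from a deterministic method-of-moments start, so fits are
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = ["MixedModelFit", "fit_day_site_lmm", "IdentifiabilityError"]

log = logging.getLogger(__name__)

_BOUNDARY_EPS = 1e-6  # relative factor below which a component is pinned to 0


class IdentifiabilityError(ValueError):
    """Raised when the panel cannot identify the requested random effects."""


@dataclass
class MixedModelFit:
    """Fitted parameters of the day/site crossed mixed model."""

    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    Sigma: np.ndarray          # 2x2 day random-effect covariance
    sigma_s_sq: float          # site random-intercept variance
    sigma_sq: float            # residual variance
    u: np.ndarray              # per-day intercept deviations (BLUPs)
    v: np.ndarray              # per-day slope deviations (BLUPs)
    s: np.ndarray              # per-site intercept deviations (BLUPs)
    day_labels: np.ndarray
    site_labels: np.ndarray
    n_days: int
    n_sites: int
    n_obs: int
    converged: bool
    loglik: float              # restricted log-likelihood
    message: str = ""
    site_cells: list | None = None  # optional (row, col) per site

    def day_effects(self, day_label) -> tuple[float, float]:
        """(u_j, v_j) for a training day label."""
        idx = np.flatnonzero(self.day_labels == day_label)
        if idx.size == 0:
            raise KeyError(f"day {day_label!r} not in training set")
        j = int(idx[0])
        return float(self.u[j]), float(self.v[j])

    def has_day(self, day_label) -> bool:
        return bool(np.any(self.day_labels == day_label))


def _design(y, x, day_idx, site_idx, include_day, include_site):
    n = y.size
    X = np.column_stack([np.ones(n), x])
    blocks = []
    J = int(day_idx.max()) + 1 if include_day else 0
    I = int(site_idx.max()) + 1 if include_site else 0
    if include_day:
        Zd = np.zeros((n, 2 * J))
        rows = np.arange(n)
        Zd[rows, 2 * day_idx] = 1.0
        Zd[rows, 2 * day_idx + 1] = x
        blocks.append(Zd)
    if include_site:
        Zs = np.zeros((n, I))
        Zs[np.arange(n), site_idx] = 1.0
        blocks.append(Zs)
    Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return X, Z, J, I


class _RemlWorkspace:
    """Precomputed cross-products; evaluates the profiled REML objective."""

    def __init__(self, y, X, Z, J, I):
        self.n, self.p = X.shape
        self.J, self.I = J, I
        self.qd = 2 * J
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    # -- structured products with the block-diagonal factor W ------------

    def _Wt_mul(self, M, Lam, g_s):
        """W' @ M for M of shape (q, k)."""
        out = np.empty_like(M)
        if self.qd:
            D = M[: self.qd].reshape(self.J, 2, -1)
            out[: self.qd] = np.einsum("ba,jbk->jak", Lam, D).reshape(self.qd, -1)
        if self.I:
            out[self.qd:] = g_s * M[self.qd:]
        return out

    def _mul_W(self, M, Lam, g_s):
        """M @ W for M of shape (k, q)."""
        out = np.empty_like(M)
        if self.qd:
            C = M[:, : self.qd].reshape(-1, self.J, 2)
            out[:, : self.qd] = np.einsum("kjb,ba->kja", C, Lam).reshape(-1, self.qd)
        if self.I:
            out[:, self.qd:] = g_s * M[:, self.qd:]
        return out

    def _W_mul_vec(self, vec, Lam, g_s):
        """W @ vec."""
        out = np.empty_like(vec)
        if self.qd:
            V = vec[: self.qd].reshape(self.J, 2)
            out[: self.qd] = (V @ Lam.T).ravel()
        if self.I:
            out[self.qd:] = g_s * vec[self.qd:]
        return out

    # -- profiled REML objective ------------------------------------------

    def _factor(self, Lam, g_s):
        q = self.qd + self.I
        AtA = self._Wt_mul(self._mul_W(self.ZtZ, Lam, g_s), Lam, g_s)
        M = AtA + np.eye(q)
        cf = cho_factor(M, lower=True)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        AtX = self._Wt_mul(self.ZtX, Lam, g_s)
        Aty = self._Wt_mul(self.Zty.reshape(-1, 1), Lam, g_s).ravel()
        MinvAtX = cho_solve(cf, AtX)
        MinvAty = cho_solve(cf, Aty)
        XtV0X = self.XtX - AtX.T @ MinvAtX
        XtV0y = self.Xty - AtX.T @ MinvAty
        ytV0y = self.yty - Aty @ MinvAty
        beta = np.linalg.solve(XtV0X, XtV0y)
        rss = max(ytV0y - beta @ XtV0y, 1e-300)
        return cf, logdet_M, XtV0X, XtV0y, beta, rss

    def neg2_reml(self, Lam, g_s):
        try:
            _, logdet_M, XtV0X, _, _, rss = self._factor(Lam, g_s)
        except np.linalg.LinAlgError:
            return 1e30
        nmp = self.n - self.p
        sign, logdet_X = np.linalg.slogdet(XtV0X)
        if sign <= 0:
            return 1e30
        sigma2 = rss / nmp
        return (
            logdet_M
            + logdet_X
            + nmp * (np.log(sigma2) + 1.0 + np.log(2.0 * np.pi))
        )


def _mom_start(y, x, day_idx, site_idx, include_day, include_site):
    """Method-of-moments start on the relative (sigma^2-scaled) scale.

    Per-day OLS intercepts/slopes give the day-effect covariance start;
    per-site residual means give the site-variance start.  Deterministic,
    and usually close to the REML optimum.
    """
    X = np.column_stack([np.ones_like(x), x])
    b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ b_ols
    s2 = max(float(resid @ resid) / max(y.size - 2, 1), 1e-12)

    theta0 = []
    if include_day:
        J = int(day_idx.max()) + 1
        ints, slopes = [], []
        for j in range(J):
            m = day_idx == j
            if m.sum() >= 3 and np.std(x[m]) > 1e-12:
                bj = np.polyfit(x[m], y[m], 1)
                slopes.append(bj[0])
                ints.append(bj[1])
        if len(ints) >= 3:
            var_u = max(np.var(ints) - s2, 0.01 * s2)
            var_v = max(np.var(slopes) - s2 / max(np.var(x), 1e-6), 0.01 * s2)
        else:
            var_u = var_v = 0.5 * s2
        theta0 += [np.sqrt(var_u / s2), 0.0,
                   np.sqrt(var_v / s2)]
    if include_site:
        I = int(site_idx.max()) + 1
        site_means = np.array([
            resid[site_idx == i].mean() if np.any(site_idx == i) else 0.0
            for i in range(I)
        ])
        var_s = max(np.var(site_means), 0.01 * s2)
        theta0 += [np.sqrt(var_s / s2)]
    return np.asarray(theta0)


def _unpack_theta(theta, include_day, include_site):
    k = 0
    Lam = np.zeros((2, 2))
    g_s = 0.0
    if include_day:
        Lam[0, 0], Lam[1, 0], Lam[1, 1] = theta[k], theta[k + 1], theta[k + 2]
        k += 3
    if include_site:
        g_s = theta[k]
        k += 1
    return Lam, g_s


def fit_day_site_lmm(
    y: Sequence[float],
    x: Sequence[float],
    day_idx: Sequence[int],
    site_idx: Sequence[int],
    day_labels: Sequence | None = None,
    site_labels: Sequence | None = None,
    include_day: bool = True,
    include_site: bool = True,
    maxiter: int = 4000,
) -> MixedModelFit:
    """Fit PM = (alpha+u_j) + (beta+v_j) x + s_i + eps by REML.

    ``day_idx`` and ``site_idx`` are dense 0-based integer codes.
    ``include_day`` / ``include_site`` force the corresponding variance
    components to zero (used for model-reduction checks); with both off
    the fit is exactly pooled ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    day_idx = np.asarray(day_idx, dtype=int)
    site_idx = np.asarray(site_idx, dtype=int)
    n = y.size
    if not (x.size == n and day_idx.size == n and site_idx.size == n):
        raise ValueError("y, x, day_idx, site_idx must have equal length")
    n_days = int(day_idx.max()) + 1 if n else 0
    n_sites = int(site_idx.max()) + 1 if n else 0
    if include_day and n_days < 2:
        raise IdentifiabilityError(
            "day random effects need >= 2 distinct days"
        )
    if include_site and n_sites < 2:
        raise IdentifiabilityError(
            "site random intercepts need >= 2 distinct sites"
        )
    if n < 5:
        raise IdentifiabilityError("panel too small to fit")

    X, Z, J, I = _design(y, x, day_idx, site_idx, include_day, include_site)
    ws = _RemlWorkspace(y, X, Z, J, I)

    if not include_day and not include_site:
        # pooled OLS
        beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta_hat
        sigma2 = float(resid @ resid) / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        ll = -0.5 * (
            (n - 2) * (np.log(sigma2) + 1 + np.log(2 * np.pi))
            + np.linalg.slogdet(X.T @ X / sigma2)[1]
        )
        return MixedModelFit(
            alpha=float(beta_hat[0]), beta=float(beta_hat[1]),
            alpha_se=float(np.sqrt(cov[0, 0])), beta_se=float(np.sqrt(cov[1, 1])),
            Sigma=np.zeros((2, 2)), sigma_s_sq=0.0, sigma_sq=sigma2,
            u=np.zeros(n_days), v=np.zeros(n_days), s=np.zeros(n_sites),
            day_labels=_labels(day_labels, n_days),
            site_labels=_labels(site_labels, n_sites),
            n_days=n_days, n_sites=n_sites, n_obs=n,
            converged=True, loglik=float(ll), message="pooled OLS (no random effects)",
        )

    theta0 = _mom_start(y, x, day_idx, site_idx, include_day, include_site)

    def objective(theta):
        Lam, g_s = _unpack_theta(theta, include_day, include_site)
        return ws.neg2_reml(Lam, g_s)

    # quasi-Newton with numerical gradients, then a simplex polish; both
    # deterministic, and the polish guards the rare L-BFGS-B stall
    res = minimize(
        objective, theta0, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    res2 = minimize(
        objective, res.x, method="Nelder-Mead",
        options={"maxiter": maxiter, "maxfev": maxiter,
                 "xatol": 1e-8, "fatol": 1e-10},
    )
    if res2.fun <= res.fun:
        res = res2
    Lam, g_s = _unpack_theta(res.x, include_day, include_site)
    # likelihood depends only on Lam Lam' and g_s^2; canonicalise signs
    if Lam[0, 0] < 0:
        Lam[:, 0] *= -1
    if Lam[1, 1] < 0:
        Lam[:, 1] *= -1
    g_s = abs(g_s)

    cf, logdet_M, XtV0X, XtV0y, beta_hat, rss = ws._factor(Lam, g_s)
    nmp = n - 2
    sigma2 = rss / nmp
    cov_fe = sigma2 * np.linalg.inv(XtV0X)

    # BLUPs: b = W M^{-1} A' r  (data scale)
    Ztr = ws.Zty - ws.ZtX @ beta_hat
    Atr = ws._Wt_mul(Ztr.reshape(-1, 1), Lam, g_s).ravel()
    b = ws._W_mul_vec(cho_solve(cf, Atr), Lam, g_s)

    u = b[0: 2 * J: 2] if include_day else np.zeros(n_days)
    v = b[1: 2 * J: 2] if include_day else np.zeros(n_days)
    s = b[2 * J:] if include_site else np.zeros(n_sites)

    Sigma = sigma2 * (Lam @ Lam.T) if include_day else np.zeros((2, 2))
    sigma_s_sq = sigma2 * g_s ** 2 if include_site else 0.0

    message = res.message
    scale = float(np.max(np.abs(res.x))) if res.x.size else 0.0
    boundary = []
    if include_day and abs(Lam[0, 0]) < _BOUNDARY_EPS * max(scale, 1.0):
        boundary.append("day intercept variance")
    if include_day and abs(Lam[1, 1]) < _BOUNDARY_EPS * max(scale, 1.0):
        boundary.append("day slope variance")
    if include_site and g_s < _BOUNDARY_EPS * max(scale, 1.0):
        boundary.append("site variance")
    if boundary:
        message += f"; components at boundary (~0): {', '.join(boundary)}"
        log.warning("fit_day_site_lmm: variance component(s) at boundary: %s",
                    ", ".join(boundary))
    if not res.success:
        log.warning("fit_day_site_lmm: optimizer did not converge: %s", res.message)

    loglik = -0.5 * res.fun
    return MixedModelFit(
        alpha=float(beta_hat[0]), beta=float(beta_hat[1]),
        alpha_se=float(np.sqrt(cov_fe[0, 0])),
        beta_se=float(np.sqrt(cov_fe[1, 1])),
        Sigma=Sigma, sigma_s_sq=float(sigma_s_sq), sigma_sq=float(sigma2),
        u=np.asarray(u, dtype=float), v=np.asarray(v, dtype=float),
        s=np.asarray(s, dtype=float),
        day_labels=_labels(day_labels, n_days),
        site_labels=_labels(site_labels, n_sites),
        n_days=n_days, n_sites=n_sites, n_obs=n,
        converged=bool(res.success), loglik=float(loglik), message=str(message),
    )


def _labels(labels, n):
    if labels is None:
        return np.arange(n)
    labels = np.asarray(labels)
    if labels.size != n:
        raise ValueError(f"expected {n} labels, got {labels.size}")
    return labels
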