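"""Poisson generalized linear mixed models by Laplace approximation.

Fits log-link Poisson mixed models with an exposure offset and crossed
Gaussian random intercepts, including an observation-level random effect
(one level per data row) used to absorb overdispersion:

    y_i ~ Poisson(mu_i),   log mu_i = offset_i + x_i' beta + sum_b u_{b, g_b(i)}

with u_b ~ N(0, sigma_b^2 I) independently per grouping factor b.

Estimation profiles the random effects and fixed effects at their joint
penalized-likelihood mode (a Newton/PIRLS inner loop) and evaluates the
Laplace approximation to the marginal log-likelihood; the variance
parameters are then maximised with a derivative-free bounded optimizer
(Nelder-Mead simplex with box bounds), in the spirit of the
bound-constrained derivative-free optimizers commonly used for such
models.  The observation-level block
is eliminated analytically (it is diagonal), so each inner Newton step
costs one dense Cholesky of size (#dates + #sessions + p).

With all variance parameters fixed at zero the fit reduces exactly to a
plain Poisson GLM, which provides a closed-form oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

__all__ = ["GlmmFit", "fit_poisson_glmm"]

_ETA_MAX = 40.0  # guard against overflow during line search


@dataclass
class GlmmFit:
    """A fitted Poisson mixed model."""

    coef: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    re_sd: dict[str, float]
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_obs: int
    fitted: np.ndarray
    ranef: dict[str, np.ndarray] = field(default_factory=dict)
    offset: np.ndarray | None = None
    optimizer_message: str = ""

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame({
            "estimate": self.coef,
            "se": self.se,
            "z": z,
        })


def _as_codes(values, n: int) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(values))
    if len(codes) != n:
        raise ValueError("group vector length does not match response")
    return codes.astype(np.int64), len(uniques)


class _Problem:
    """Preprocessed design for one model; holds the warm-started state."""

    def __init__(self, y, X, offset, groups, obs_group):
        self.y = y
        self.offset = offset
        self.n = len(y)
        self.Xnames = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"x{j}" for j in range(np.asarray(X).shape[1])]
        self.X = np.asarray(X, dtype=float)
        self.p = self.X.shape[1]
        self.obs_group = obs_group
        self.dense_groups: list[tuple[str, np.ndarray, int]] = []
        for name, codes in groups.items():
            if name == obs_group:
                continue
            c, q = _as_codes(codes, self.n)
            self.dense_groups.append((name, c, q))
        # dense block = [group indicators ..., X]
        cols = []
        self.slices: dict[str, slice] = {}
        start = 0
        for name, c, q in self.dense_groups:
            Z = np.zeros((self.n, q))
            Z[np.arange(self.n), c] = 1.0
            cols.append(Z)
            self.slices[name] = slice(start, start + q)
            start += q
        self.beta_slice = slice(start, start + self.p)
        cols.append(self.X)
        self.D = np.hstack(cols) if cols else np.zeros((self.n, 0))
        self.m = self.D.shape[1]
        self.u_cols = np.arange(0, self.beta_slice.start)
        # warm-start state
        self.gamma = np.zeros(self.m)
        self.e = np.zeros(self.n)

    def _penalty(self, sds: dict[str, float]) -> np.ndarray:
        pen = np.zeros(self.m)
        for name, _, _ in self.dense_groups:
            pen[self.slices[name]] = 1.0 / sds[name] ** 2
        return pen

    def _objective(self, gamma, e, pen, inv_so2):
        eta = self.offset + self.D @ gamma + e
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        f = float(self.y @ eta - mu.sum())
        f -= 0.5 * float(pen @ gamma**2)
        if inv_so2 is not None:
            f -= 0.5 * inv_so2 * float(e @ e)
        return f, eta, mu

    def solve_mode(self, sds: dict[str, float], obs_sd: float | None,
                   max_iter: int = 60, tol: float = 1e-9):
        """Newton/PIRLS for the joint penalized mode; warm-started."""
        pen = self._penalty(sds)
        inv_so2 = None if obs_sd is None else 1.0 / obs_sd**2
        gamma, e = self.gamma.copy(), (self.e.copy() if obs_sd is not None
                                       else np.zeros(self.n))
        if obs_sd is None:
            e[:] = 0.0
        f, eta, mu = self._objective(gamma, e, pen, inv_so2)
        S = None
        converged = False
        for _ in range(max_iter):
            w = mu
            resid = self.y - mu
            g_gamma = self.D.T @ resid - pen * gamma
            if inv_so2 is not None:
                g_e = resid - inv_so2 * e
                d = w + inv_so2
                weff = w - w**2 / d
                rhs = g_gamma - self.D.T @ (w * g_e / d)
            else:
                g_e = None
                d = None
                weff = w
                rhs = g_gamma
            S = (self.D.T * weff) @ self.D
            S[np.diag_indices_from(S)] += pen
            try:
                c, low = _chol(S)
            except np.linalg.LinAlgError:
                S[np.diag_indices_from(S)] += 1e-8 * (1 + np.abs(np.diag(S)))
                c, low = _chol(S)
            from scipy.linalg import cho_solve
            dgamma = cho_solve((c, low), rhs)
            if inv_so2 is not None:
                de = (g_e - w * (self.D @ dgamma)) / d
            else:
                de = 0.0
            step = 1.0
            grad_norm = np.max(np.abs(rhs)) if rhs.size else 0.0
            for _ in range(40):
                g_new = gamma + step * dgamma
                e_new = e + step * de if inv_so2 is not None else e
                f_new, eta_new, mu_new = self._objective(g_new, e_new, pen,
                                                         inv_so2)
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    break
                step *= 0.5
            improve = f_new - f
            gamma, e, f, eta, mu = g_new, e_new, f_new, eta_new, mu_new
            if improve < tol * (1.0 + abs(f)) and grad_norm < 1e-4 * (
                    1.0 + np.abs(self.y).sum()):
                converged = True
                break
            if improve < 1e-13 * (1.0 + abs(f)):
                converged = True
                break
        self.gamma, self.e = gamma.copy(), e.copy()
        return gamma, e, f, eta, mu, S, converged

    def laplace_loglik(self, sds: dict[str, float], obs_sd: float | None):
        """Laplace marginal log-likelihood at the profiled mode."""
        gamma, e, _, eta, mu, S, conv = self.solve_mode(sds, obs_sd)
        pen = self._penalty(sds)
        inv_so2 = None if obs_sd is None else 1.0 / obs_sd**2
        ll = float(self.y @ eta - mu.sum() - gammaln(self.y + 1.0).sum())
        ll -= 0.5 * float(pen @ gamma**2)
        for name, _, q in self.dense_groups:
            ll -= 0.5 * q * np.log(sds[name] ** 2)
        logdet = 0.0
        if inv_so2 is not None:
            d = mu + inv_so2
            ll -= 0.5 * inv_so2 * float(e @ e)
            ll -= 0.5 * self.n * np.log(obs_sd**2)
            logdet += float(np.log(d).sum())
        if len(self.u_cols):
            Su = S[np.ix_(self.u_cols, self.u_cols)]
            sign, ld = np.linalg.slogdet(Su)
            if sign <= 0:
                return -np.inf, conv, S, mu
            logdet += float(ld)
        ll -= 0.5 * logdet
        return ll, conv, S, mu


def _chol(S):
    from scipy.linalg import cho_factor
    return cho_factor(S, lower=True)


def fit_poisson_glmm(
    response,
    design,
    offset=None,
    groups: dict | None = None,
    obs_group: str = "observation",
    fix_sd: dict[str, float] | None = None,
    start_sd: float = 0.2,
    sd_bounds: tuple[float, float] = (1e-4, 3.0),
    maxfev: int = 250,
) -> GlmmFit:
    """Fit a Poisson GLMM with log link, offset, and crossed random intercepts.

    Parameters
    ----------
    response : array of non-negative integers
        Counts (click density per minute in this package's analysis).
    design : DataFrame or 2-D array
        Fixed-effect design matrix including the intercept column.
    offset : array or None
        Log-scale exposure offset (e.g. ``log(n_individuals)``); zero if None.
    groups : dict mapping factor name -> per-row level labels
        Random-intercept grouping factors.  A factor whose name equals
        ``obs_group`` (or that has one level per row) is treated as the
        observation-level effect and eliminated analytically.
    fix_sd : dict, optional
        Standard deviations to hold fixed instead of estimating; a value of
        0 removes that random effect entirely (the SD->0 limit).
    """
    y = np.asarray(response, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integers")
    n = len(y)
    if isinstance(design, pd.DataFrame):
        X = design
    else:
        X = pd.DataFrame(np.asarray(design, dtype=float))
        X.columns = [f"x{j}" for j in X.columns]
    if len(X) != n:
        raise ValueError("design and response lengths differ")
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    groups = dict(groups or {})
    fix_sd = dict(fix_sd or {})

    # identify the observation-level factor
    obs_name = None
    for name, codes in groups.items():
        c, q = _as_codes(codes, n)
        if name == obs_group or q == n:
            obs_name = name
    # groups fixed at sd 0 are dropped outright
    dropped = {name for name, v in fix_sd.items() if v == 0.0}
    active = {name: codes for name, codes in groups.items()
              if name not in dropped}
    has_obs = obs_name is not None and obs_name not in dropped

    dense_names = [name for name in active if name != obs_name]
    prob = _Problem(y, X, offset,
                    {name: active[name] for name in dense_names},
                    obs_group=None)

    free_names = [name for name in dense_names if name not in fix_sd]
    free_obs = has_obs and obs_name not in fix_sd

    def unpack(theta):
        sds = {}
        i = 0
        for name in dense_names:
            if name in fix_sd:
                sds[name] = float(fix_sd[name])
            else:
                sds[name] = float(np.exp(theta[i])); i += 1
        if has_obs:
            obs_sd = (float(fix_sd[obs_name]) if obs_name in fix_sd
                      else float(np.exp(theta[i])))
        else:
            obs_sd = None
        return sds, obs_sd

    n_free = len(free_names) + (1 if free_obs else 0)
    opt_message = "no variance parameters estimated"
    opt_success = True
    if n_free:
        lo, hi = np.log(sd_bounds[0]), np.log(sd_bounds[1])
        theta0 = np.full(n_free, np.log(start_sd))

        def neg_ll(theta):
            sds, obs_sd = unpack(theta)
            ll, _, _, _ = prob.laplace_loglik(sds, obs_sd)
            return -ll if np.isfinite(ll) else 1e12

        res = optimize.minimize(
            neg_ll, theta0, method="Nelder-Mead",
            bounds=[(lo, hi)] * n_free,
            options={"xatol": 1e-2, "fatol": 1e-3, "maxfev": maxfev},
        )
        theta_hat = res.x
        opt_message = res.message
        opt_success = bool(res.success)
    else:
        theta_hat = np.zeros(0)

    sds, obs_sd = unpack(theta_hat)
    ll, inner_conv, S, mu = prob.laplace_loglik(sds, obs_sd)
    gamma, e = prob.gamma, prob.e

    # covariance of the dense block = inverse of the Schur complement
    from scipy.linalg import cho_factor, cho_solve
    try:
        c, low = cho_factor(S, lower=True)
        cov_dense = cho_solve((c, low), np.eye(S.shape[0]))
    except np.linalg.LinAlgError:
        cov_dense = np.linalg.pinv(S)
    bs = prob.beta_slice
    cov_beta = cov_dense[bs, bs]
    coef = pd.Series(gamma[bs], index=prob.Xnames)
    se = pd.Series(np.sqrt(np.maximum(np.diag(cov_beta), 0.0)),
                   index=prob.Xnames)
    cov = pd.DataFrame(cov_beta, index=prob.Xnames, columns=prob.Xnames)

    re_sd = {name: sds[name] for name in dense_names}
    if has_obs:
        re_sd[obs_name] = float(obs_sd)
    for name in dropped:
        re_sd[name] = 0.0
    ranef = {name: gamma[prob.slices[name]].copy() for name in dense_names}
    if has_obs:
        ranef[obs_name] = e.copy()

    k = prob.p + n_free
    aic = -2.0 * ll + 2.0 * k
    eta = offset + prob.D @ gamma + (e if has_obs else 0.0)
    fitted = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    return GlmmFit(
        coef=coef, se=se, cov=cov, re_sd=re_sd,
        loglik=float(ll), aic=float(aic), n_params=k,
        converged=bool(inner_conv and opt_success), n_obs=n,
        fitted=fitted, ranef=ranef, offset=offset,
        optimizer_message=str(opt_message),
    )
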