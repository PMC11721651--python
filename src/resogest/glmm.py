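"""Mixed-effects logistic regression with crossed random intercepts.

Fits ``logit P(y=1) = X beta + sum_k u_k[group_k]`` with independent Gaussian
random intercepts ``u_k ~ N(0, sigma_k^2 I)`` per grouping factor, by maximum
likelihood under the Laplace approximation: the marginal likelihood integral
over the random effects is replaced by its Gaussian approximation around the
joint posterior mode, the same approximation lme4's ``glmer`` uses by
default.  Intended for the modest dimensions of multiparty-conversation
designs (tens of random-effect levels); the mode is found by damped Newton
on the dense joint Hessian.

Numerical notes: variance components are optimised on the log-sd scale with
box bounds, so boundary (singular) fits come out as sigma ~ exp(lower
bound) ~ 0 rather than failing; the conditional log-likelihood uses
``logaddexp`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LogisticMixedModel", "LogisticMixedResults"]

_LOG_SD_BOUNDS = (-6.0, 3.0)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


@dataclass
class LogisticMixedResults:
    """ML estimates of a Laplace-fitted mixed logit."""

    params: np.ndarray  # fixed effects
    bse: np.ndarray
    exog_names: list[str]
    group_names: list[str]
    sigmas: np.ndarray  # random-intercept SDs, one per grouping factor
    llf: float  # Laplace marginal log-likelihood
    random_effects: dict[str, pd.Series]  # conditional modes per factor
    converged: bool
    nobs: int
    model: "LogisticMixedModel" = field(repr=False)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        lines = [
            "Mixed logistic regression (Laplace ML)",
            f"  nobs = {self.nobs}, logLik = {self.llf:.3f}, "
            f"converged = {self.converged}",
            "  Fixed effects:",
        ]
        for name, b, se, z, p in zip(
            self.exog_names, self.params, self.bse, self.zvalues,
            self.pvalues,
        ):
            lines.append(
                f"    {name:<20s} {b:10.4f}  SE {se:8.4f}  "
                f"z {z:7.3f}  p {p:9.3g}"
            )
        lines.append("  Random intercept SDs:")
        for name, s in zip(self.group_names, self.sigmas):
            lines.append(f"    {name:<20s} {s:10.4f}")
        return "\n".join(lines)


class LogisticMixedModel:
    """Binary-outcome mixed model with crossed random intercepts.

    Parameters
    ----------
    endog : array-like of 0/1
    exog : (n, p) design matrix including the intercept column
    groups : mapping of factor name -> length-n label array
    exog_names : optional fixed-effect column names
    """

    def __init__(self, endog, exog, groups: dict, exog_names=None):
        self.y = np.asarray(endog, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != self.y.size:
            self.X = self.X.T
        n, p = self.X.shape
        if n != self.y.size:
            raise ValueError("endog/exog length mismatch")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError(
                "outcome takes a single value; mixed logit is not "
                "identifiable"
            )
        self.exog_names = (
            list(exog_names) if exog_names is not None
            else [f"x{j}" for j in range(p)]
        )
        self.group_names = list(groups)
        self.codes = []
        self.levels = []
        for name in self.group_names:
            labels = pd.Series(list(groups[name]))
            cats = pd.Categorical(labels)
            self.codes.append(np.asarray(cats.codes, dtype=int))
            self.levels.append(list(cats.categories))
        self.sizes = [len(lv) for lv in self.levels]
        self.offsets = np.concatenate(
            [[0], np.cumsum(self.sizes)]
        ).astype(int)
        self.q = int(self.offsets[-1])

    # -- joint-mode machinery ------------------------------------------------

    def _eta(self, beta, u):
        eta = self.X @ beta
        for k, codes in enumerate(self.codes):
            eta = eta + u[self.offsets[k] + codes]
        return eta

    def _cond_ll(self, eta):
        return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))

    def _penalty(self, u, inv_var):
        return 0.5 * float(np.sum(u * u * inv_var))

    def _inv_var_vector(self, sigmas):
        return np.concatenate(
            [np.full(m, 1.0 / max(s, 1e-12) ** 2)
             for m, s in zip(self.sizes, sigmas)]
        )

    def _joint_hessian(self, w, inv_var):
        H = np.zeros((self.q, self.q))
        for k, ck in enumerate(self.codes):
            ok = self.offsets[k]
            np.add.at(H, (ok + ck, ok + ck), w)
            for j in range(k + 1, len(self.codes)):
                oj = self.offsets[j]
                np.add.at(H, (ok + ck, oj + self.codes[j]), w)
        H = H + np.triu(H, 1).T
        H[np.diag_indices_from(H)] += inv_var
        return H

    def _find_mode(self, beta, sigmas, u0=None):
        """Damped Newton ascent of the penalised conditional log-likelihood."""
        inv_var = self._inv_var_vector(sigmas)
        u = np.zeros(self.q) if u0 is None else u0.copy()
        obj = self._cond_ll(self._eta(beta, u)) - self._penalty(u, inv_var)
        for _ in range(50):
            eta = self._eta(beta, u)
            p = _expit(eta)
            resid = self.y - p
            grad = np.concatenate(
                [np.bincount(c, weights=resid, minlength=m)
                 for c, m in zip(self.codes, self.sizes)]
            ) - u * inv_var
            if np.max(np.abs(grad)) < 1e-9:
                break
            w = np.maximum(p * (1.0 - p), 1e-10)
            H = self._joint_hessian(w, inv_var)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad / np.diag(H)
            lam = 1.0
            for _ in range(30):
                u_new = u + lam * step
                obj_new = (
                    self._cond_ll(self._eta(beta, u_new))
                    - self._penalty(u_new, inv_var)
                )
                if obj_new >= obj - 1e-12:
                    break
                lam *= 0.5
            if obj_new < obj - 1e-10:
                break
            u, obj = u_new, obj_new
        return u

    def loglike(self, beta, sigmas, u0=None):
        """Laplace marginal log-likelihood and the conditional mode."""
        u = self._find_mode(beta, sigmas, u0)
        inv_var = self._inv_var_vector(sigmas)
        eta = self._eta(beta, u)
        p = _expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = self._joint_hessian(w, inv_var)
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, u
        logdet_sigma = float(
            np.sum([2 * m * np.log(max(s, 1e-12))
                    for m, s in zip(self.sizes, sigmas)])
        )
        ll = (
            self._cond_ll(eta)
            - self._penalty(u, inv_var)
            - 0.5 * logdet_sigma
            - 0.5 * logdet_h
        )
        return float(ll), u

    # -- fitting -------------------------------------------------------------

    def _theta_ll(self, theta, warm):
        p = self.X.shape[1]
        beta, log_sd = theta[:p], theta[p:]
        ll, u = self.loglike(beta, np.exp(log_sd), warm.get("u"))
        warm["u"] = u
        return ll

    def fit(self, start_params=None, maxiter=200,
            compute_se=True) -> LogisticMixedResults:
        n, p = self.X.shape
        if start_params is None:
            import statsmodels.api as sm

            with np.errstate(all="ignore"):
                beta0 = sm.Logit(self.y, self.X).fit(
                    disp=0, maxiter=100, method="lbfgs"
                ).params
            beta0 = np.nan_to_num(np.asarray(beta0), nan=0.0)
        else:
            beta0 = np.asarray(start_params, dtype=float)
        theta0 = np.concatenate(
            [beta0, np.full(len(self.group_names), np.log(0.5))]
        )
        warm: dict = {}
        neg = lambda th: -self._theta_ll(th, warm)
        bounds = [(-30.0, 30.0)] * p + [_LOG_SD_BOUNDS] * len(
            self.group_names
        )
        res = optimize.minimize(
            neg, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
        )
        beta = res.x[:p]
        sigmas = np.exp(res.x[p:])
        llf, u_hat = self.loglike(beta, sigmas, warm.get("u"))
        bse = (self._wald_se(res.x, warm) if compute_se
               else np.full(p, np.nan))
        re = {}
        for k, name in enumerate(self.group_names):
            sl = slice(self.offsets[k], self.offsets[k + 1])
            re[name] = pd.Series(u_hat[sl], index=self.levels[k])
        return LogisticMixedResults(
            params=beta,
            bse=bse,
            exog_names=self.exog_names,
            group_names=self.group_names,
            sigmas=sigmas,
            llf=llf,
            random_effects=re,
            converged=bool(res.success),
            nobs=n,
            model=self,
        )

    def _wald_se(self, theta, warm) -> np.ndarray:
        """Fixed-effect SEs from a finite-difference Hessian of the Laplace
        log-likelihood at the optimum."""
        p = self.X.shape[1]
        d = len(theta)
        h = 1e-4 * np.maximum(1.0, np.abs(theta))
        f = lambda th: self._theta_ll(th, warm)
        H = np.zeros((d, d))
        f0 = f(theta)
        fp = np.empty(d)
        fm = np.empty(d)
        for i in range(d):
            e = np.zeros(d)
            e[i] = h[i]
            fp[i] = f(theta + e)
            fm[i] = f(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                e_i = np.zeros(d)
                e_j = np.zeros(d)
                e_i[i], e_j[j] = h[i], h[j]
                fpp = f(theta + e_i + e_j)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + f0
                ) / (h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            var = np.diag(cov)[:p]
            return np.sqrt(np.where(var > 0, var, np.nan))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)
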