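"""Negative-binomial count models for interval bat activity.

The response is the bat-pass count per analysis interval, modelled as
NB2 (variance ``mu + mu^2 / theta``) with a log link.  A site ("location")
random intercept accounts for repeated measures; its marginal likelihood
is evaluated by a Laplace approximation, and following the parsimony rule
used throughout, the random effect is dropped when its fitted variance
falls below 1e-4.  Model selection is information-theoretic: candidate
confounders are screened univariately at p <= 0.1, all subsets of the
surviving fixed effects are ranked by AICc, and coefficients are averaged
over the dAICc <= 6 set with Akaike weights (full, zero-substituted
averaging).  Contrasts between interval categories are reported as
incidence rate ratios, exp(coefficient).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "AveragedModel",
    "fit_nb",
    "screen_univariate",
    "rank_and_average",
    "pairwise_contrasts",
    "lr_test_random_effect",
    "aicc",
    "quantile_residuals",
]

#: random-effect variance below which the intercept is removed for parsimony
RE_VAR_FLOOR = 1e-4


# ---------------------------------------------------------------- design

@dataclass
class ModelSpec:
    """Declarative model description over an analysis table."""

    response: str = "count"
    fixed_terms: tuple[str, ...] = ()
    random_intercept: str | None = None
    category_term: str = "category"
    reference_level: str = "between"

    def design(self, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        """Build the fixed-effects design matrix (intercept first)."""
        n = len(table)
        cols = [np.ones(n)]
        names = ["(Intercept)"]
        for term in self.fixed_terms:
            if term not in table.columns:
                raise KeyError(f"term {term!r} not in table")
            col = table[term]
            if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
                levels = (list(col.cat.categories)
                          if isinstance(col.dtype, pd.CategoricalDtype)
                          else sorted(col.dropna().unique()))
                if self.reference_level in levels:
                    levels = [self.reference_level] + [l for l in levels
                                                       if l != self.reference_level]
                for lev in levels[1:]:
                    cols.append((col == lev).to_numpy(dtype=float))
                    names.append(f"{term}[{lev}]")
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(term)
        return np.column_stack(cols), names


@dataclass
class FitResult:
    """Maximum-likelihood NB2 fit (optionally with a Laplace random intercept)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray  # fixed-effect block of the inverse observed information
    theta: float
    loglik: float
    n: int
    k: int
    aicc: float
    random_effect: str | None = None
    re_var: float = 0.0
    re_sd: float = 0.0
    re_p: float | None = None
    re_removed: bool = False
    converged: bool = True
    terms: tuple[str, ...] = ()

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.coef, "se": self.se,
            "ci_low": self.coef - 1.96 * self.se,
            "ci_high": self.coef + 1.96 * self.se,
            "z": self.z, "p": self.p,
        }, index=self.names)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------- NB2 core

def _nb_loglik_terms(y, mu, theta):
    with np.errstate(over="ignore", invalid="ignore"):
        return (special.gammaln(y + theta) - special.gammaln(theta)
                - special.gammaln(y + 1.0)
                + theta * np.log(theta / (theta + mu))
                + y * np.log(mu / (theta + mu)))


def _nb_obj(params, X, y):
    """Negative loglik and gradient over (beta, log theta)."""
    beta, ltheta = params[:-1], min(params[-1], 30.0)  # theta cap: Poisson limit
    theta = math.exp(ltheta)
    eta = X @ beta
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    ll = _nb_loglik_terms(y, mu, theta).sum()
    with np.errstate(over="ignore", invalid="ignore"):
        w = (y - mu) * theta / (theta + mu)
        g_beta = X.T @ w
        g_ltheta = theta * np.sum(
            special.digamma(y + theta) - special.digamma(theta)
            + np.log(theta / (theta + mu)) + 1.0 - (y + theta) / (theta + mu))
    return -ll, -np.concatenate([g_beta, [g_ltheta]])


@dataclass
class _FitInfo:
    x: np.ndarray
    success: bool


def _start_values(X, y):
    z = np.log(y + 0.5)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return beta


def _fit_nb_fixed(X, y, start=None):
    """ML fit of fixed-effects NB2 over (beta, log theta)."""
    p = X.shape[1]
    if start is None:
        start = np.concatenate([_start_values(X, y), [0.0]])
    res = optimize.minimize(_nb_obj, start, args=(X, y), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    # polish with a second pass from the solution (helps tight tolerance)
    res2 = optimize.minimize(_nb_obj, res.x, args=(X, y), jac=True,
                             method="BFGS", options={"gtol": 1e-9, "maxiter": 200})
    if res2.fun <= res.fun:
        res = res2
    x = res.x.copy()
    # Newton polish: beta step with analytic information, then 1-D theta step
    x[-1] = min(x[-1], 30.0)
    for _ in range(25):
        beta, theta = x[:p], math.exp(min(x[-1], 30.0))
        mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
        w = theta * mu * (theta + y) / (theta + mu) ** 2
        _, g = _nb_obj(x, X, y)
        if np.max(np.abs(g)) < 1e-10:
            break
        H = (X * w[:, None]).T @ X
        try:
            db = np.linalg.solve(H, -g[:p])
        except np.linalg.LinAlgError:
            break
        eps = 1e-6
        gp = _nb_obj(np.r_[x[:-1], x[-1] + eps], X, y)[1][-1]
        gm = _nb_obj(np.r_[x[:-1], x[-1] - eps], X, y)[1][-1]
        h_t = (gp - gm) / (2 * eps)
        dt = -g[-1] / h_t if h_t > 0 else 0.0
        step = np.r_[db, dt]
        xn = x + np.clip(step, -2.0, 2.0)
        if _nb_obj(xn, X, y)[0] <= _nb_obj(x, X, y)[0] + 1e-12:
            x = xn
        else:
            break
    beta = x[:p]
    theta = math.exp(min(x[-1], 30.0))
    f, g = _nb_obj(x, X, y)
    ll = -f
    # convergence judged on the final (polished) gradient, scaled by n
    converged = bool(np.max(np.abs(g[:p])) < 1e-4 * max(len(y), 1))
    return beta, theta, ll, _FitInfo(x=x, success=converged)


def _num_hessian(fun, x, eps=1e-5):
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


# ------------------------------------------------------- Laplace intercept

def _laplace_negll(params, X, y, starts, gix, u_cache):
    """Negative Laplace marginal loglik over (beta, log theta, log sigma)."""
    p = X.shape[1]
    beta, ltheta, lsigma = params[:p], min(params[p], 30.0), params[p + 1]
    theta = math.exp(ltheta)
    sig2 = math.exp(2.0 * lsigma)
    eta = np.clip(X @ beta, -30.0, 30.0)
    u = u_cache.copy()
    G = starts.size
    # vectorised per-group Newton for the conditional modes
    for _ in range(60):
        mu = np.exp(np.clip(eta + u[gix], -30.0, 30.0))
        s1 = (y - mu) * theta / (theta + mu)
        s2 = theta * mu * (theta + y) / (theta + mu) ** 2
        g1 = np.add.reduceat(s1, starts) - u / sig2
        g2 = -np.add.reduceat(s2, starts) - 1.0 / sig2
        step = np.clip(g1 / g2, -3.0, 3.0)  # damped for stability
        u = u - step
        if np.max(np.abs(step)) < 3e-9:
            break
    u_cache[:] = u
    mu = np.exp(np.clip(eta + u[gix], -30.0, 30.0))
    ll_cond = _nb_loglik_terms(y, mu, theta)
    s2 = theta * mu * (theta + y) / (theta + mu) ** 2
    h = np.add.reduceat(s2, starts) + 1.0 / sig2
    ll = (np.sum(ll_cond) - np.sum(u ** 2) / (2 * sig2)
          - 0.5 * G * math.log(sig2) - 0.5 * np.sum(np.log(h)))
    return -ll


def _fit_nb_laplace(X, y, groups, start=None):
    codes, _ = pd.factorize(groups, sort=True)
    order = np.argsort(codes, kind="stable")
    Xo, yo, co = X[order], y[order], codes[order]
    starts = np.flatnonzero(np.r_[1, np.diff(co)])
    counts = np.diff(np.r_[starts, co.size])
    gix = np.repeat(np.arange(starts.size), counts)
    u_cache = np.zeros(starts.size)

    p = X.shape[1]
    if start is None:
        b0, th0, *_ = _fit_nb_fixed(X, y)
        start = np.concatenate([b0, [math.log(th0)], [math.log(0.3)]])
    obj = lambda prm: _laplace_negll(prm, Xo, yo, starts, gix, u_cache)
    # gtol sits above the forward-difference noise floor of the objective
    # (|f| ~ n); curvature ~ n keeps the coefficient error near 1e-6
    res = optimize.minimize(obj, start, method="BFGS",
                            options={"gtol": 1e-3, "maxiter": 200})
    # BFGS with a numeric gradient can stall on this objective; a simplex
    # pass from its solution (or the start) recovers the optimum reliably
    x0 = res.x if np.isfinite(res.fun) else start
    res_nm = optimize.minimize(obj, x0, method="Nelder-Mead",
                               options={"maxiter": 2000, "xatol": 1e-6,
                                        "fatol": 1e-8})
    if res_nm.fun < res.fun or not np.isfinite(res.fun):
        res = res_nm
    beta = res.x[:p]
    theta = math.exp(res.x[p])
    sigma = math.exp(res.x[p + 1])
    ll = -res.fun
    info = _FitInfo(x=res.x, success=bool(np.isfinite(ll)))
    return beta, theta, sigma, ll, info, obj


def fit_nb(spec: ModelSpec, table: pd.DataFrame, re_lrt: bool = False,
           start: np.ndarray | None = None) -> FitResult:
    """Fit the NB2 model described by ``spec`` to an analysis table.

    With a random intercept requested, the marginal likelihood is
    maximised under the Laplace approximation; if the fitted variance is
    below 1e-4 the model is refit without the random effect and flagged
    (``re_removed``).  ``re_lrt=True`` additionally reports a boundary-
    corrected likelihood-ratio p-value for the variance component.
    """
    X, names = spec.design(table)
    y = table[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integers")
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few rows for the requested model")

    if spec.random_intercept is None:
        beta, theta, ll, res = _fit_nb_fixed(X, y, start)
        k = p + 1
        # beta and theta are information-orthogonal in NB2, so the beta
        # covariance is the inverse expected information at fixed theta
        mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
        w = theta * mu / (theta + mu)
        cov = _safe_inv((X * w[:, None]).T @ X)
        return FitResult(names=names, coef=beta, se=np.sqrt(np.diag(cov)),
                         cov=cov, theta=theta, loglik=ll, n=n, k=k,
                         aicc=aicc(ll, k, n), converged=bool(res.success),
                         terms=tuple(spec.fixed_terms))

    groups = table[spec.random_intercept].to_numpy()
    beta, theta, sigma, ll, res, obj = _fit_nb_laplace(X, y, groups, start)
    if sigma ** 2 < RE_VAR_FLOOR:
        fixed_spec = ModelSpec(response=spec.response, fixed_terms=spec.fixed_terms,
                               random_intercept=None,
                               category_term=spec.category_term,
                               reference_level=spec.reference_level)
        out = fit_nb(fixed_spec, table)
        out.re_removed = True
        out.random_effect = None
        return out

    k = p + 2  # beta, theta, sigma
    x_hat = np.concatenate([beta, [math.log(theta)], [math.log(sigma)]])
    H = _num_hessian(obj, x_hat, eps=1e-4)
    cov_all = _safe_inv(H)
    cov = cov_all[:p, :p]
    if not np.all(np.isfinite(np.diag(cov))) or np.any(np.diag(cov) <= 0):
        # ill-conditioned numeric Hessian: fall back to the conditional
        # expected information (ignores random-effect uncertainty)
        mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
        w = theta * mu / (theta + mu)
        cov = _safe_inv((X * w[:, None]).T @ X)
    re_p = None
    if re_lrt:
        _, _, ll0, _ = _fit_nb_fixed(X, y)
        fit0 = FitResult(names=names, coef=beta, se=np.zeros(p), cov=cov,
                         theta=theta, loglik=ll0, n=n, k=p + 1,
                         aicc=aicc(ll0, p + 1, n))
        fit1 = FitResult(names=names, coef=beta, se=np.zeros(p), cov=cov,
                         theta=theta, loglik=ll, n=n, k=k, aicc=aicc(ll, k, n),
                         random_effect=spec.random_intercept)
        re_p = lr_test_random_effect(fit1, fit0)
    return FitResult(names=names, coef=beta, se=np.sqrt(np.diag(cov)),
                     cov=cov, theta=theta, loglik=ll, n=n, k=k,
                     aicc=aicc(ll, k, n), random_effect=spec.random_intercept,
                     re_var=sigma ** 2, re_sd=sigma, re_p=re_p,
                     converged=bool(res.success), terms=tuple(spec.fixed_terms))


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def lr_test_random_effect(fit_with: FitResult, fit_without: FitResult) -> float:
    """Boundary-corrected LRT p-value for the random-intercept variance.

    The null places the variance on the boundary of the parameter space,
    so the statistic is referred to an equal mixture of chi2(0) and
    chi2(1): p = 0.5 * P(chi2_1 > LR).
    """
    if fit_with.n != fit_without.n:
        raise ValueError("fits must be on identical data")
    if fit_without.random_effect is not None or fit_with.random_effect is None:
        raise ValueError("expected (mixed, fixed) fit pair")
    lr = max(2.0 * (fit_with.loglik - fit_without.loglik), 0.0)
    return 0.5 * float(stats.chi2.sf(lr, df=1))


# ------------------------------------------------------------- selection

def screen_univariate(candidates: list[str], table: pd.DataFrame,
                      base_spec: ModelSpec | None = None,
                      alpha: float = 0.1) -> list[str]:
    """Keep candidates univariately associated with activity at p <= alpha.

    Each candidate is fitted alone (with the same random structure as the
    final models); it is retained iff any of its coefficients has
    p <= alpha (boundary inclusive).
    """
    base_spec = base_spec or ModelSpec()
    kept = []
    for term in candidates:
        spec = ModelSpec(response=base_spec.response, fixed_terms=(term,),
                         random_intercept=base_spec.random_intercept,
                         category_term=base_spec.category_term,
                         reference_level=base_spec.reference_level)
        fit = fit_nb(spec, table)
        if np.any(fit.p[1:] <= alpha):
            kept.append(term)
    return kept


@dataclass
class AveragedModel:
    """Akaike-weight average of the dAICc <= 6 model set (full averaging)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    members: list[FitResult]
    delta_aicc: np.ndarray
    weights: np.ndarray           # renormalised over the member set
    full_set_weights: np.ndarray  # over every candidate subset, sums to 1
    full_set_terms: list[tuple[str, ...]]
    category_term: str = "category"
    reference_level: str = "between"

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.coef / self.se, np.inf * np.sign(self.coef))

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(np.where(np.isfinite(self.z), self.z, 0.0)))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.coef, "se": self.se,
            "ci_low": self.coef - 1.96 * self.se,
            "ci_high": self.coef + 1.96 * self.se,
            "z": self.z, "p": self.p,
        }, index=self.names)


def rank_and_average(full_terms: list[str], table: pd.DataFrame,
                     base_spec: ModelSpec | None = None,
                     delta_max: float = 6.0) -> AveragedModel:
    """All-subsets AICc ranking and full model averaging.

    Every subset of ``full_terms`` (including the intercept-only model) is
    fitted with the base random structure; models within ``delta_max``
    AICc of the best form the averaged set.  Averaging is full
    (zero-substituted): a model that omits a term contributes a zero
    coefficient with zero variance.  The adjusted SE folds in
    between-model spread: se_j = sum_m w_m * sqrt(se_jm^2 + (b_jm - bbar_j)^2).
    """
    if len(full_terms) > 12:
        raise ValueError("more than 12 fixed terms; all-subsets fit refused")
    base_spec = base_spec or ModelSpec()

    # order of reporting: union of coefficient names over the full model
    full_spec = _with_terms(base_spec, tuple(full_terms))
    _, all_names = full_spec.design(table)
    name_ix = {nm: i for i, nm in enumerate(all_names)}

    # warm starts: seed every subset fit from the full-model coefficients
    full_fit = fit_nb(full_spec, table)
    full_by_name = dict(zip(full_fit.names, full_fit.coef))

    fits: list[FitResult] = []
    subsets: list[tuple[str, ...]] = []
    for r in range(len(full_terms) + 1):
        for combo in itertools.combinations(full_terms, r):
            spec = _with_terms(base_spec, combo)
            _, sub_names = spec.design(table.iloc[:2]) if len(table) >= 2 else (None, None)
            start = np.array([full_by_name.get(nm, 0.0) for nm in sub_names]
                             + [math.log(full_fit.theta)])
            if base_spec.random_intercept is not None:
                start = np.r_[start, math.log(max(full_fit.re_sd, 0.05))]
            try:
                fit = fit_nb(spec, table, start=start)
            except Exception as exc:  # non-convergence: exclude with warning
                warnings.warn(f"model {combo!r} failed to fit: {exc}")
                continue
            if not fit.converged:
                warnings.warn(f"model {combo!r} did not converge; excluded")
                continue
            fits.append(fit)
            subsets.append(combo)

    if not fits:
        raise RuntimeError("no candidate model converged")
    aiccs = np.array([f.aicc for f in fits])
    # deterministic tie-break: lexicographic by term names at equal AICc
    order = sorted(range(len(fits)), key=lambda i: (aiccs[i], subsets[i]))
    fits = [fits[i] for i in order]
    subsets = [subsets[i] for i in order]
    aiccs = aiccs[order]
    delta_all = aiccs - aiccs[0]
    w_all = np.exp(-0.5 * delta_all)
    w_all = w_all / w_all.sum()

    member_ix = np.flatnonzero(delta_all <= delta_max)
    members = [fits[i] for i in member_ix]
    delta = delta_all[member_ix]
    w = w_all[member_ix] / w_all[member_ix].sum()

    P = len(all_names)
    B = np.zeros((len(members), P))
    S = np.zeros((len(members), P))
    for m, fit in enumerate(members):
        for nm, b, s in zip(fit.names, fit.coef, fit.se):
            j = name_ix[nm]
            B[m, j] = b
            S[m, j] = s
    coef = w @ B
    se = np.einsum("m,mj->j", w, np.sqrt(S ** 2 + (B - coef) ** 2))
    return AveragedModel(names=all_names, coef=coef, se=se, members=members,
                         delta_aicc=delta, weights=w, full_set_weights=w_all,
                         full_set_terms=subsets,
                         category_term=base_spec.category_term,
                         reference_level=base_spec.reference_level)


def _with_terms(base: ModelSpec, terms: tuple[str, ...]) -> ModelSpec:
    return ModelSpec(response=base.response, fixed_terms=terms,
                     random_intercept=base.random_intercept,
                     category_term=base.category_term,
                     reference_level=base.reference_level)


# ------------------------------------------------------------- contrasts

def _contrast_vec(names: list[str], term: str, a: str, b: str, ref: str) -> np.ndarray:
    """Coefficient-space vector for the (a vs b) log-rate difference."""
    v = np.zeros(len(names))
    if a != ref:
        v[names.index(f"{term}[{a}]")] = 1.0
    if b != ref:
        v[names.index(f"{term}[{b}]")] = -1.0
    return v


def pairwise_contrasts(model: FitResult | AveragedModel,
                       category_term: str | None = None,
                       levels: tuple[str, str, str] = ("before", "after", "between"),
                       reference: str | None = None) -> pd.DataFrame:
    """All three pairwise interval-category contrasts as IRRs.

    Point estimates and SEs are those obtained by re-levelling the
    reference category; for averaged models the re-levelled averaging is
    evaluated as the weighted linear combination of member-model
    contrasts (identical, since averaging is linear in the coefficients
    and AICc ranking does not depend on the reference level).
    """
    if isinstance(model, AveragedModel):
        term = category_term or model.category_term
        ref = reference or model.reference_level
        names = model.names
    else:
        term = category_term or "category"
        ref = reference or "between"
        names = model.names
    lev = [l for l in levels]
    dummy = [nm for nm in names if nm.startswith(f"{term}[")]
    if len(dummy) < 2:
        raise ValueError("category term must have 3 levels in the model")

    pairs = [("before", "between"), ("after", "between"), ("after", "before")]
    rows = []
    for a, b in pairs:
        v = _contrast_vec(names, term, a, b, ref)
        if isinstance(model, AveragedModel):
            ests, ses = [], []
            for fit in model.members:
                vm = np.array([v[names.index(nm)] for nm in fit.names])
                if np.any(vm != 0):
                    est_m = float(vm @ fit.coef)
                    se_m = float(np.sqrt(vm @ fit.cov @ vm))
                else:
                    est_m, se_m = 0.0, 0.0
                ests.append(est_m)
                ses.append(se_m)
            ests = np.array(ests)
            ses = np.array(ses)
            est = float(model.weights @ ests)
            se = float(model.weights @ np.sqrt(ses ** 2 + (ests - est) ** 2))
        else:
            est = float(v @ model.coef)
            se = float(np.sqrt(v @ model.cov @ v))
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        rows.append({
            "contrast": f"{a} vs {b}", "estimate": est, "se": se,
            "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
            "z": z, "p": p, "irr": math.exp(est),
            "irr_low": math.exp(est - 1.96 * se),
            "irr_high": math.exp(est + 1.96 * se),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------- diagnostics

def quantile_residuals(fit: FitResult, spec: ModelSpec, table: pd.DataFrame,
                       seed: int = 0) -> np.ndarray:
    """Randomised quantile residuals; ~U(0,1) under a correct model."""
    X, _ = spec.design(table)
    y = table[spec.response].to_numpy(dtype=float)
    mu = np.exp(np.clip(X @ fit.coef, -30, 30))
    th = fit.theta
    rng = np.random.default_rng(seed)
    lo = stats.nbinom.cdf(y - 1, th, th / (th + mu))
    hi = stats.nbinom.cdf(y, th, th / (th + mu))
    return lo + rng.uniform(size=y.size) * (hi - lo)
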