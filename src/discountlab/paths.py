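"""Path analysis of anxiety effects on discounting, with optional mediation.

A recursive system of observed-variable regressions is estimated jointly by
normal-theory maximum likelihood on the sample covariance matrix (the
lavaan-style discrepancy function), with standard errors from the observed
information.  The models used here regress the experiential and hypothetical
willingness-to-wait measures (model-based AUC) on state and trait anxiety,
optionally inserting perceptual reward sensitivity as a mediator of the
state effect; exogenous variances/covariance, outcome residual variances and
the outcome residual covariance are free, mirroring a saturated (or
near-saturated) covariance structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = [
    "PathSpec",
    "PathFit",
    "NO_MEDIATION",
    "WITH_MEDIATION",
    "fit_path",
    "fit_indices",
    "indirect_effect",
    "moderation_regression",
    "split_half_groups",
]


@dataclass(frozen=True)
class PathSpec:
    """Recursive path model over observed variables.

    ``equations`` maps each endogenous variable to its regressor tuple, in
    causal order; ``exogenous`` lists the source variables whose variances
    and pairwise covariances are free; ``residual_covs`` lists endogenous
    pairs with a free residual covariance.
    """

    exogenous: tuple[str, ...]
    equations: dict[str, tuple[str, ...]]
    residual_covs: tuple[tuple[str, str], ...] = ()

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.exogenous) + tuple(self.equations)

    def n_free_params(self) -> int:
        k = len(self.exogenous)
        n_exo = k * (k + 1) // 2
        n_beta = sum(len(v) for v in self.equations.values())
        return n_exo + n_beta + len(self.equations) + len(self.residual_covs)

    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_params()


NO_MEDIATION = PathSpec(
    exogenous=("state_anxiety", "trait_anxiety"),
    equations={
        "auc_experiential": ("state_anxiety", "trait_anxiety"),
        "auc_hypothetical": ("state_anxiety", "trait_anxiety"),
    },
    residual_covs=(("auc_experiential", "auc_hypothetical"),),
)

WITH_MEDIATION = PathSpec(
    exogenous=("state_anxiety", "trait_anxiety"),
    equations={
        "reward_sensitivity": ("state_anxiety", "trait_anxiety"),
        "auc_experiential": ("state_anxiety", "trait_anxiety", "reward_sensitivity"),
        "auc_hypothetical": ("state_anxiety", "trait_anxiety"),
    },
    residual_covs=(("auc_experiential", "auc_hypothetical"),),
)


@dataclass
class PathFit:
    spec: PathSpec
    estimates: dict[tuple[str, str], float]        # (outcome, regressor) -> beta
    se: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    std_estimates: dict[tuple[str, str], float]    # fully standardized
    std_x_estimates: dict[tuple[str, str], float]  # predictors-only standardized
    r2: dict[str, float]
    implied_cov: pd.DataFrame
    sample_cov: pd.DataFrame
    loglik: float
    n: int
    converged: bool

    @property
    def df(self) -> int:
        return self.spec.df()


def _pack_indices(spec: PathSpec):
    """Free-parameter layout: exogenous cov (lower tri), betas, resid vars,
    resid covs."""
    exo = spec.exogenous
    layout = []
    for i, a in enumerate(exo):
        for b in exo[: i + 1]:
            layout.append(("exo", a, b))
    for out, regs in spec.equations.items():
        for r in regs:
            layout.append(("beta", out, r))
    for out in spec.equations:
        layout.append(("psi", out, out))
    for a, b in spec.residual_covs:
        layout.append(("psi", a, b))
    return layout


def _implied_cov(theta, spec: PathSpec, layout) -> np.ndarray:
    names = list(spec.variables)
    idx = {v: i for i, v in enumerate(names)}
    p = len(names)
    B = np.zeros((p, p))        # regression coefficients (row = outcome)
    Psi = np.zeros((p, p))      # exogenous cov + residual (co)variances
    for val, (kind, a, b) in zip(theta, layout):
        if kind == "exo":
            Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = val
        elif kind == "beta":
            B[idx[a], idx[b]] = val
        else:
            Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = val
    inv = np.linalg.inv(np.eye(p) - B)
    return inv @ Psi @ inv.T


def _ols_start(data: pd.DataFrame, spec: PathSpec, layout) -> np.ndarray:
    theta = []
    S = np.cov(data[list(spec.variables)].to_numpy().T, ddof=1)
    names = list(spec.variables)
    resid = {}
    for out, regs in spec.equations.items():
        X = sm.add_constant(data[list(regs)].to_numpy())
        fit = sm.OLS(data[out].to_numpy(), X).fit()
        resid[out] = fit.resid
        for r, b in zip(regs, fit.params[1:]):
            resid.setdefault("_beta", {})[(out, r)] = b
    betas = resid.get("_beta", {})
    for kind, a, b in layout:
        if kind == "exo":
            theta.append(S[names.index(a), names.index(b)])
        elif kind == "beta":
            theta.append(betas[(a, b)])
        elif a == b:
            theta.append(float(np.var(resid[a], ddof=1)))
        else:
            theta.append(float(np.cov(resid[a], resid[b], ddof=1)[0, 1]))
    return np.asarray(theta, dtype=float)


def _ml_discrepancy(theta, spec, layout, S):
    sigma = _implied_cov(theta, spec, layout)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def fit_path(data: pd.DataFrame, spec: PathSpec) -> PathFit:
    """Normal-theory ML fit of a recursive path model.

    Equation-wise least squares supplies starting values (and, for recursive
    models with shared regressor sets, already solves the ML problem); the
    ML discrepancy is then minimized over all free parameters and standard
    errors are taken from the observed information of the log-likelihood.
    """
    cols = list(spec.variables)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns {missing}")
    d = data[cols].dropna()
    n = len(d)
    if n <= spec.n_free_params():
        raise ValueError("need more complete cases than free parameters")
    S = np.cov(d.to_numpy().T, ddof=1)
    if np.any(np.linalg.eigvalsh(S) < -1e-10):
        raise ValueError("sample covariance is not positive semi-definite")

    layout = _pack_indices(spec)
    theta0 = _ols_start(d, spec, layout)
    res = optimize.minimize(
        _ml_discrepancy, theta0, args=(spec, layout, S), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 2000},
    )
    theta = res.x
    sigma = _implied_cov(theta, spec, layout)

    # observed information of logL = -(n/2) * (log|Sigma| + tr(S Sigma^-1) + c)
    def negloglik(t):
        return 0.5 * n * _ml_discrepancy(t, spec, layout, S)

    hess = _numeric_hessian(negloglik, theta)
    try:
        cov_theta = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        ses = np.full_like(theta, np.nan)

    names = list(spec.variables)
    sds = {v: math.sqrt(S[names.index(v), names.index(v)]) for v in names}
    estimates, se_map, pvals, std_full, std_x = {}, {}, {}, {}, {}
    for val, s, (kind, a, b) in zip(theta, ses, layout):
        if kind != "beta":
            continue
        estimates[(a, b)] = float(val)
        se_map[(a, b)] = float(s)
        z = val / s if s > 0 else np.inf
        pvals[(a, b)] = float(2.0 * stats.norm.sf(abs(z)))
        std_full[(a, b)] = float(val * sds[b] / sds[a])
        std_x[(a, b)] = float(val * sds[b])

    r2 = {}
    for out in spec.equations:
        i = names.index(out)
        psi = dict(zip([tuple(x) for x in layout], theta))[("psi", out, out)]
        r2[out] = float(1.0 - psi / sigma[i, i])

    loglik = float(-0.5 * n * (_ml_discrepancy(theta, spec, layout, S)
                               + np.linalg.slogdet(S)[1] + len(names)
                               + len(names) * math.log(2 * math.pi)))
    return PathFit(
        spec=spec,
        estimates=estimates,
        se=se_map,
        p_values=pvals,
        std_estimates=std_full,
        std_x_estimates=std_x,
        r2=r2,
        implied_cov=pd.DataFrame(sigma, index=names, columns=names),
        sample_cov=pd.DataFrame(S, index=names, columns=names),
        loglik=loglik,
        n=n,
        converged=bool(res.success or res.fun < _ml_discrepancy(theta0, spec, layout, S)),
    )


def _numeric_hessian(f, x, h=1e-5):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xi = x.copy(); xi[i] += h; xi[j] += h
            xj = x.copy(); xj[i] += h
            xk = x.copy(); xk[j] += h
            H[i, j] = H[j, i] = (f(xi) - f(xj) - f(xk) + f0) / (h * h)
    return H


def fit_indices(fit: PathFit) -> tuple[float, float, float]:
    """(CFI, RMSEA, SRMR) of a fitted path model.

    CFI compares the model chi-square to the independence baseline; RMSEA
    derives from the noncentrality (chi2 - df)/(df (n-1)); SRMR is the root
    mean squared standardized residual moment.  Saturated models return
    CFI = 1 and RMSEA = 0 exactly.
    """
    n, df = fit.n, fit.df
    S = fit.sample_cov.to_numpy()
    sigma = fit.implied_cov.to_numpy()
    p = S.shape[0]

    # SRMR over the standardized lower triangle including the diagonal
    d = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(d, d)
    tri = resid[np.tril_indices(p)]
    srmr = float(np.sqrt(np.mean(tri ** 2)))

    if df == 0:
        return 1.0, 0.0, srmr

    f_model = _discrepancy_from_cov(S, sigma)
    chi2 = (n - 1) * f_model
    base_sigma = np.diag(np.diag(S))
    chi2_base = (n - 1) * _discrepancy_from_cov(S, base_sigma)
    df_base = p * (p - 1) // 2
    cfi = 1.0 - max(chi2 - df, 0.0) / max(chi2_base - df_base, chi2 - df, 1e-12)
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
    return float(cfi), float(rmsea), srmr


def _discrepancy_from_cov(S, sigma):
    sign, logdet = np.linalg.slogdet(sigma)
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - S.shape[0])


def indirect_effect(fit: PathFit, predictor: str, mediator: str, outcome: str
                    ) -> tuple[float, float, float]:
    """Product-of-paths indirect effect with the delta-method SE."""
    try:
        a = fit.estimates[(mediator, predictor)]
        b = fit.estimates[(outcome, mediator)]
    except KeyError as exc:
        raise ValueError(
            f"spec has no {predictor}->{mediator}->{outcome} mediation path"
        ) from exc
    sa = fit.se[(mediator, predictor)]
    sb = fit.se[(outcome, mediator)]
    est = a * b
    se = math.sqrt(max(a * a * sb * sb + b * b * sa * sa, 0.0))
    z = est / se if se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(est), float(se), p


def moderation_regression(auc, state, trait) -> pd.DataFrame:
    """OLS of AUC on state, trait and their raw-score product.

    Returns a coefficient table (term, coef, se, t, p) with the model F, R2
    and residual df attached as DataFrame attrs.
    """
    auc = np.asarray(auc, dtype=float)
    state = np.asarray(state, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if not (auc.shape == state.shape == trait.shape) or auc.size < 10:
        raise ValueError("need equal-length vectors with n >= 10")
    X = np.column_stack([state, trait, state * trait])
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(state), X])) < 4:
        raise ValueError("regressors are collinear to machine precision")
    fit = sm.OLS(auc, sm.add_constant(X)).fit()
    table = pd.DataFrame({
        "term": ["intercept", "state", "trait", "state_x_trait"],
        "coef": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    table.attrs.update({
        "f_stat": float(fit.fvalue), "f_p": float(fit.f_pvalue),
        "r2": float(fit.rsquared),
        "df_model": int(fit.df_model), "df_resid": int(fit.df_resid),
    })
    return table


def split_half_groups(trait, auc, state) -> pd.DataFrame:
    """Median split on trait anxiety; state-AUC Pearson r within each half."""
    trait = np.asarray(trait, dtype=float)
    auc = np.asarray(auc, dtype=float)
    state = np.asarray(state, dtype=float)
    if trait.size < 10:
        raise ValueError("need n >= 10 for a split-half illustration")
    med = np.median(trait)
    low = trait <= med
    if max(low.sum(), (~low).sum()) > 0.6 * trait.size:
        import warnings

        warnings.warn("median ties place > 60% of participants in one half")
    rows = []
    for name, mask in (("low_trait", low), ("high_trait", ~low)):
        r, p = stats.pearsonr(state[mask], auc[mask])
        rows.append({"group": name, "n": int(mask.sum()), "r": float(r),
                     "p": float(p)})
    return pd.DataFrame(rows)
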