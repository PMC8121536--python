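"""Linearized mixed-model framework for discounting and pleasantness data.

The logit-style transform Y = log((1 - SV')/SV') linearizes both discounting
families: the hyperbolic model becomes Y = log k + log T (slope on log T
fixed to 1, so only random/fixed intercepts are estimated), and the logistic
model becomes Y = -a b + a log T with per-participant intercept and slope.
All models are fit by maximum likelihood (never REML) so that AIC/BIC and
likelihood-ratio comparisons across fixed-effect structures are valid.

Indifference points at the extreme grid levels give SV' of exactly 0 or 1,
where the transform diverges.  Two conventions are offered: ``boundary=
"drop"`` (default) excludes those observations from the fit, which is the
convention consistent with steep recovered group slopes; ``boundary=
"clamp"`` winsorizes SV' by a config-derived eps before transforming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .task import TaskConfig

__all__ = [
    "LmmFit",
    "LrtResult",
    "logit_transform",
    "inverse_logit_transform",
    "grid_eps",
    "prepare_lmm_dataset",
    "fit_lmm",
    "compare_lmm",
    "nakagawa_r2",
    "fit_pleasantness",
]

LmmModel = Literal["null", "hyperbolic", "logistic"]


def logit_transform(sv_norm, eps: float = 0.01):
    """Y = log((1 - p)/p) with p = clamp(SV', eps, 1 - eps).

    Strictly decreasing in SV'; eps keeps the transform finite at the
    boundary values the staircase can actually produce.
    """
    sv_norm = np.asarray(sv_norm, dtype=float)
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    if np.any(sv_norm < -1e-12) or np.any(sv_norm > 1 + 1e-12):
        raise ValueError("sv_norm must lie in [0, 1]")
    p = np.clip(sv_norm, eps, 1.0 - eps)
    return np.log((1.0 - p) / p)


def inverse_logit_transform(y):
    """SV' = 1/(1 + e^y); inverse of the transform on (eps, 1 - eps)."""
    y = np.asarray(y, dtype=float)
    return 1.0 / (1.0 + np.exp(y))


def grid_eps(config: TaskConfig) -> float:
    """Half the smallest normalized level step of a task grid."""
    v = np.asarray(config.immediate_values, dtype=float) / config.delayed_value
    v_norm = (v - v[0]) / (1.0 - v[0])
    return float(np.min(np.diff(v_norm)) / 2.0)


def prepare_lmm_dataset(
    points: pd.DataFrame,
    config: TaskConfig,
    boundary: Literal["drop", "clamp"] = "drop",
) -> pd.DataFrame:
    """Indifference-point table -> (participant_id, log_delay, y) rows.

    ``value`` is normalized against the task's minimum subjective value and
    logit-transformed.  Boundary rows (SV' in {0, 1}) are dropped or clamped
    per ``boundary``.
    """
    sv_min = config.sv_min
    frac = points["value"].to_numpy(dtype=float) / config.delayed_value
    sv_norm = (np.clip(frac, sv_min, 1.0) - sv_min) / (1.0 - sv_min)
    eps = grid_eps(config)
    out = pd.DataFrame({
        "participant_id": points["participant_id"].to_numpy(),
        "log_delay": np.log(points["delay"].to_numpy(dtype=float)),
        "sv_norm": sv_norm,
    })
    if boundary == "drop":
        keep = (sv_norm > eps / 2) & (sv_norm < 1 - eps / 2)
        out = out.loc[keep].reset_index(drop=True)
    elif boundary != "clamp":
        raise ValueError("boundary must be 'drop' or 'clamp'")
    out["y"] = logit_transform(out["sv_norm"].to_numpy(), eps=eps)
    return out


@dataclass
class LmmFit:
    model: str
    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    random_sd: dict[str, float]
    residual_sd: float
    loglik: float
    n_params: int
    n_obs: int
    n_groups: int
    converged: bool
    diagnostics: str = ""
    _var_fixed: float = field(default=0.0, repr=False)
    _var_random: float = field(default=0.0, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float
    note: str = ""


def _fit_mixedlm(endog, data, exog_cols, groups, re_formula_cols, offset=None):
    """Shared ML MixedLM driver returning (result, converged, message)."""
    y = np.asarray(endog, dtype=float)
    if offset is not None:
        y = y - np.asarray(offset, dtype=float)
    X = np.column_stack([np.ones_like(y)] + [np.asarray(data[c], float) for c in exog_cols])
    exog_re = np.column_stack(
        [np.ones_like(y)] + [np.asarray(data[c], float) for c in re_formula_cols]
    )
    model = sm.regression.mixed_linear_model.MixedLM(
        y, X, groups=np.asarray(groups), exog_re=exog_re
    )
    converged, message = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="bfgs", maxiter=1000)
            converged = bool(getattr(res, "converged", True))
            if not np.isfinite(res.llf):
                raise RuntimeError("non-finite log-likelihood")
        except Exception as exc:  # singular fits flagged, not raised
            res = model.fit(reml=False, method="powell", maxiter=2000)
            converged = bool(getattr(res, "converged", False))
            message = str(exc)
    return res, converged, message


def _package_fit(name, res, exog_names, re_names, data, exog_cols, converged, message,
                 n_params):
    groups_n = len(np.unique(res.model.groups))
    fe = {n: float(v) for n, v in zip(exog_names, res.fe_params)}
    se = {n: float(v) for n, v in zip(exog_names, res.bse_fe)}
    # random-effect covariance is reported on the residual-variance scale
    cov_re = np.asarray(res.cov_re) * res.scale
    random_sd = {n: float(np.sqrt(max(cov_re[i, i], 0.0)))
                 for i, n in enumerate(re_names)}
    # variance components for marginal/conditional R2
    X = res.model.exog
    var_fixed = float(np.var(X @ res.fe_params))
    Z = res.model.exog_re
    var_random = float(np.mean(np.einsum("ij,jk,ik->i", Z, cov_re, Z)))
    return LmmFit(
        model=name,
        fixed_effects=fe,
        fixed_se=se,
        random_sd=random_sd,
        residual_sd=float(np.sqrt(res.scale)),
        loglik=float(res.llf),
        n_params=n_params,
        n_obs=int(res.model.endog.shape[0]),
        n_groups=groups_n,
        converged=converged,
        diagnostics=message,
        _var_fixed=var_fixed,
        _var_random=var_random,
    )


def fit_lmm(data: pd.DataFrame, model: LmmModel) -> LmmFit:
    """ML mixed model on transformed indifference points.

    null:       Y_ij = b0i                      (random intercept)
    hyperbolic: Y_ij = b0i + log T_j            (log T offset, coefficient 1)
    logistic:   Y_ij = b0i + b1i log T_j        (correlated intercept/slope)
    """
    required = {"participant_id", "log_delay", "y"}
    if not required.issubset(data.columns):
        raise ValueError(f"dataset must contain columns {sorted(required)}")
    if data["participant_id"].nunique() < 2 or data["log_delay"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 distinct delays")
    groups = data["participant_id"]
    if model == "null":
        res, conv, msg = _fit_mixedlm(data["y"], data, [], groups, [])
        return _package_fit("null", res, ["intercept"], ["intercept"],
                            data, [], conv, msg, n_params=3)
    if model == "hyperbolic":
        res, conv, msg = _fit_mixedlm(data["y"], data, [], groups, [],
                                      offset=data["log_delay"])
        fit = _package_fit("hyperbolic", res, ["intercept"], ["intercept"],
                           data, [], conv, msg, n_params=3)
        # fixed-effect variance must credit the unit-coefficient log T term
        fit._var_fixed = float(np.var(fit.fixed_effects["intercept"]
                                      + data["log_delay"].to_numpy(float)))
        return fit
    if model == "logistic":
        res, conv, msg = _fit_mixedlm(data["y"], data, ["log_delay"], groups,
                                      ["log_delay"])
        # params: 2 fixed + 3 random-covariance + 1 residual
        return _package_fit("logistic", res, ["intercept", "log_delay"],
                            ["intercept", "log_delay"], data, ["log_delay"],
                            conv, msg, n_params=6)
    raise ValueError(f"unknown model {model!r}")


_NESTING = {
    ("null", "hyperbolic"), ("null", "logistic"), ("hyperbolic", "logistic"),
    ("pleasantness_null", "pleasantness_fixed"),
    ("pleasantness_null", "pleasantness_full"),
    ("pleasantness_fixed", "pleasantness_full"),
}


def compare_lmm(fit0: LmmFit, fit1: LmmFit) -> LrtResult:
    """Likelihood-ratio test of nested ML fits; chi2 floored at 0.

    Comparisons whose counted parameter difference is zero (the hyperbolic
    model replaces the null's free mean structure with a fixed-offset term)
    are reported with df = 0 and a note; the chi-square p-value is then taken
    as the point-mass limit (p -> 0 for any positive deviance change).
    """
    if (fit0.model, fit1.model) not in _NESTING and fit0.model != fit1.model:
        raise ValueError(f"{fit0.model!r} is not nested in {fit1.model!r}")
    if fit0.n_obs != fit1.n_obs:
        raise ValueError("fits must share the same data")
    chi2 = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    df = fit1.n_params - fit0.n_params
    if df > 0:
        p = float(stats.chi2.sf(chi2, df))
        note = ""
    else:
        df = 0
        p = 1.0 if chi2 == 0.0 else 0.0
        note = "boundary comparison with zero counted-parameter difference"
    return LrtResult(chi2=float(chi2), df=int(df), p=p, note=note)


def nakagawa_r2(fit: LmmFit) -> tuple[float, float]:
    """Marginal and conditional R2 from the fit's variance components.

    marginal = var_f / (var_f + var_r + var_e); conditional adds var_r to
    the numerator.  var_r averages the random-effect variance over the
    observed design for random-slope models.
    """
    var_f, var_r = fit._var_fixed, fit._var_random
    var_e = fit.residual_sd ** 2
    total = var_f + var_r + var_e
    if total <= 0:
        raise ZeroDivisionError("total variance is zero; R2 undefined")
    return var_f / total, (var_f + var_r) / total


def fit_pleasantness(data: pd.DataFrame, random_slope: bool = True,
                     null: bool = False) -> LmmFit:
    """ML mixed model of pleasantness ratings on occlusion level.

    Fixed occlusion slope with random intercepts, plus a correlated random
    slope when ``random_slope`` (the rating-task analysis); the during-task
    variant uses occlusion only as a fixed factor.  ``null`` drops occlusion
    entirely (per-participant means only).
    """
    required = {"participant_id", "occlusion_level", "rating"}
    if not required.issubset(data.columns):
        raise ValueError(f"dataset must contain columns {sorted(required)}")
    groups = data["participant_id"]
    if null:
        res, conv, msg = _fit_mixedlm(data["rating"], data, [], groups, [])
        return _package_fit("pleasantness_null", res, ["intercept"],
                            ["intercept"], data, [], conv, msg, n_params=3)
    if random_slope:
        res, conv, msg = _fit_mixedlm(data["rating"], data, ["occlusion_level"],
                                      groups, ["occlusion_level"])
        return _package_fit("pleasantness_full", res,
                            ["intercept", "occlusion_level"],
                            ["intercept", "occlusion_level"], data,
                            ["occlusion_level"], conv, msg, n_params=6)
    res, conv, msg = _fit_mixedlm(data["rating"], data, ["occlusion_level"],
                                  groups, [])
    return _package_fit("pleasantness_fixed", res,
                        ["intercept", "occlusion_level"], ["intercept"],
                        data, ["occlusion_level"], conv, msg, n_params=4)
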