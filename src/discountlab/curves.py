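"""Discounting-curve models, per-participant least-squares fits, and AUC.

Two families describe how the normalized subjective value SV' of a delayed
reward falls with delay T:

* hyperbolic:  SV' = 1 / (1 + k T), with discount rate k > 0;
* logistic on the log-delay axis:  SV' = 1 / (1 + exp(a (log T - b))),
  where b is the log-delay at which preference switches and a the sharpness
  of the switch.

The hyperbolic curve is the one-parameter special case a = 1, b = -log k;
the power-function (Rachlin) model SV = M / (1 + k T^s) is the case
a = s, b = -log(k)/s.  Log base e throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "sv_hyperbolic",
    "sv_logistic",
    "normalize_sv",
    "denormalize_sv",
    "hyperbolic_as_logistic",
    "rachlin_as_logistic",
    "CurveFit",
    "fit_curve",
    "model_auc",
]

Model = Literal["hyperbolic", "logistic2", "logistic3"]


def sv_hyperbolic(T, k):
    """Hyperbolic subjective value 1/(1 + kT) of a unit delayed reward."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("delay T must be > 0")
    if np.any(np.asarray(k) < 0):
        raise ValueError("discount rate k must be >= 0")
    return 1.0 / (1.0 + k * T)


def sv_logistic(T, a, b):
    """Two-parameter logistic subjective value 1/(1 + e^{a(log T - b)})."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("delay T must be > 0")
    if a <= 0:
        raise ValueError("slope a must be > 0")
    x = a * (np.log(T) - b)
    # guard exp overflow far out on either tail
    x = np.clip(x, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(x))


def normalize_sv(sv, sv_min: float):
    """Map raw subjective value on [sv_min, 1] to SV' on [0, 1]."""
    sv = np.asarray(sv, dtype=float)
    if not (0.0 <= sv_min < 1.0):
        raise ValueError("sv_min must lie in [0, 1)")
    if np.any(sv < sv_min - 1e-12) or np.any(sv > 1.0 + 1e-12):
        raise ValueError("sv outside [sv_min, 1]")
    return (sv - sv_min) / (1.0 - sv_min)


def denormalize_sv(sv_norm, sv_min: float):
    """Inverse of :func:`normalize_sv`."""
    sv_norm = np.asarray(sv_norm, dtype=float)
    if not (0.0 <= sv_min < 1.0):
        raise ValueError("sv_min must lie in [0, 1)")
    return sv_min + sv_norm * (1.0 - sv_min)


def hyperbolic_as_logistic(k: float) -> tuple[float, float]:
    """Logistic parameters (a, b) = (1, -log k) of the hyperbolic curve."""
    if k <= 0:
        raise ValueError("k must be > 0")
    return 1.0, -math.log(k)


def rachlin_as_logistic(k: float, s: float) -> tuple[float, float]:
    """Logistic parameters (a, b) = (s, -log(k)/s) of M/(1 + k T^s)."""
    if k <= 0 or s <= 0:
        raise ValueError("k and s must be > 0")
    return float(s), -math.log(k) / s


@dataclass(frozen=True)
class CurveFit:
    """Least-squares fit of one participant's normalized indifference points."""

    model: Model
    params: tuple[float, ...]
    rmse: float
    r2: float
    n_points: int
    converged: bool
    bounds_hit: bool

    @property
    def k(self) -> float | None:
        return self.params[0] if self.model == "hyperbolic" else None

    @property
    def a(self) -> float | None:
        return self.params[0] if self.model.startswith("logistic") else None

    @property
    def b(self) -> float | None:
        return self.params[1] if self.model.startswith("logistic") else None

    @property
    def c(self) -> float | None:
        return self.params[2] if self.model == "logistic3" else None


def _predict(model: Model, params: Sequence[float], T: np.ndarray) -> np.ndarray:
    if model == "hyperbolic":
        return sv_hyperbolic(T, params[0])
    if model == "logistic2":
        return sv_logistic(T, params[0], params[1])
    if model == "logistic3":
        a, b, c = params
        return c + (1.0 - c) * sv_logistic(T, a, b)
    raise ValueError(f"unknown model {model!r}")


def fit_curve(
    delays: Sequence[float],
    sv_norm: Sequence[float],
    model: Model = "logistic2",
    a_starts: Sequence[float] = (0.25, 1.0, 4.0, 16.0),
    k_starts: Sequence[float] | None = None,
) -> CurveFit:
    """Bounded least squares of SV'(T) with a multi-start grid.

    Both indifference points per delay enter as separate observations.  R2 is
    reported relative to the mean of the observations and may be negative
    (the mean describes the data better than the curve); RMSE is the root of
    the mean squared residual.
    """
    T = np.asarray(delays, dtype=float)
    y = np.asarray(sv_norm, dtype=float)
    if T.shape != y.shape or T.size < 3:
        raise ValueError("need >= 3 (delay, sv_norm) observations")
    if np.unique(T).size < 2:
        raise ValueError("degenerate input: all observations at one delay")

    log_t = np.log(T)
    b_lo, b_hi = log_t.min() - 2.0, log_t.max() + 2.0

    def residuals(p):
        return _predict(model, p, T) - y

    candidates: list[tuple[np.ndarray, np.ndarray]] = []
    if model == "hyperbolic":
        if k_starts is None:
            k_starts = np.geomspace(1e-6, 10.0, 8)
        bounds = ([1e-9], [1e4])
        starts = [[k] for k in k_starts]
    elif model == "logistic2":
        b_starts = np.linspace(b_lo, b_hi, 5)
        bounds = ([1e-3, b_lo], [1e3, b_hi])
        starts = [[a, b] for a in a_starts for b in b_starts]
    else:  # logistic3, experimental: floor asymptote c
        b_starts = np.linspace(b_lo, b_hi, 5)
        bounds = ([1e-3, b_lo, 0.0], [1e3, b_hi, 0.5])
        starts = [[a, b, 0.05] for a in a_starts for b in b_starts]

    best = None
    any_converged = False
    for x0 in starts:
        try:
            res = optimize.least_squares(residuals, x0, bounds=bounds, method="trf")
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        any_converged = any_converged or res.success
        ssr = 2.0 * res.cost
        a_val = res.x[0]
        key = (round(ssr, 12), a_val)
        if best is None or key < (round(best[0], 12), best[1]):
            best = (ssr, a_val, res)
    if best is None:  # pragma: no cover
        raise RuntimeError("curve fit failed from every start")

    ssr, _, res = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else (1.0 if ssr < 1e-12 else -np.inf)
    lb, ub = np.asarray(bounds[0]), np.asarray(bounds[1])
    bounds_hit = bool(np.any(np.isclose(res.x, lb)) or np.any(np.isclose(res.x, ub)))
    return CurveFit(
        model=model,
        params=tuple(float(v) for v in res.x),
        rmse=float(np.sqrt(ssr / T.size)),
        r2=float(r2),
        n_points=int(T.size),
        converged=bool(any_converged),
        bounds_hit=bounds_hit,
    )


def model_auc(fit: CurveFit, t_min: float, t_max: float) -> float:
    """Normalized area under the fitted logistic discounting curve.

    (1/(t_max - t_min)) * integral of SV'(T) dT on the linear time axis;
    lies in [0, 1], larger = greater willingness to wait.
    """
    if fit.model != "logistic2":
        raise ValueError("model-based AUC is defined for the logistic2 fit")
    if not (0 < t_min < t_max):
        raise ValueError("need t_max > t_min > 0")
    a, b = fit.params
    # integrate on the log axis with the Jacobian e^u for numerical stability
    # at large a (the integrand is then a smooth sigmoid in u)
    u_min, u_max = math.log(t_min), math.log(t_max)

    def f(u):
        return sv_logistic(math.exp(u), a, b) * math.exp(u)

    val, _ = integrate.quad(f, u_min, u_max, points=[min(max(b, u_min), u_max)],
                            limit=200)
    return float(min(1.0, max(0.0, val / (t_max - t_min))))
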