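"""Asymptotic confidence intervals from the observed information.

The observed Fisher information is the negative Hessian of the censored
log-likelihood at the estimate; its inverse estimates the sampling
covariance and yields Wald intervals ``theta_i +/- z_{1-gamma/2} sqrt(V_ii)``.
The same construction, evaluated at the MPS estimate on the MPS
objective, provides intervals for the spacings estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .censored import TypeICensoredSample, loglik, mps_objective
from .distribution import ParamVector

__all__ = ["CIResult", "observed_information", "asymptotic_ci"]

_PARAM_NAMES = ("alpha", "beta", "lam")

_OBJECTIVES = {"mle": loglik, "mps": mps_objective}


@dataclass
class CIResult:
    """Per-parameter Wald intervals at level 1 - gamma."""

    low: np.ndarray
    high: np.ndarray
    length: np.ndarray
    level: float
    method: str
    ok: np.ndarray  # False where the variance estimate was unusable
    names: tuple = _PARAM_NAMES


def _hessian_fd(f, x0: np.ndarray, rel_step: float = 1e-4,
                richardson: bool = True) -> np.ndarray:
    """Central finite-difference Hessian, optionally Richardson-refined.

    Steps are relative, ``h_i = rel_step * max(1, |x_i|)`` with the
    default near eps**(1/4), the optimum for second differences; the
    Richardson pass combines step h and h/2 as (4 H_{h/2} - H_h)/3,
    cancelling the leading O(h^2) error.
    """
    x0 = np.asarray(x0, dtype=float)
    h = rel_step * np.maximum(1.0, np.abs(x0))

    def hess_at(step):
        p = x0.size
        H = np.empty((p, p))
        f0 = f(x0)
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = step[i]
            H[i, i] = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / step[i] ** 2
            for j in range(i + 1, p):
                ej = np.zeros(p)
                ej[j] = step[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4.0 * step[i] * step[j])
        return H

    H = hess_at(h)
    if richardson:
        H = (4.0 * hess_at(h / 2.0) - H) / 3.0
    return 0.5 * (H + H.T)


def observed_information(theta_hat: ParamVector, sample: TypeICensoredSample,
                         objective="mle", rel_step: float = 1e-4,
                         richardson: bool = True) -> np.ndarray:
    """Observed information matrix: minus the Hessian of the objective.

    ``objective`` may be "mle" (censored log-likelihood), "mps", or any
    callable ``f(theta, sample)``.  The matrix is symmetrized exactly;
    definiteness is the caller's concern (``asymptotic_ci`` suppresses
    intervals for non-positive variance estimates).
    """
    obj = _OBJECTIVES.get(objective, objective)
    if not callable(obj):
        raise ValueError(f"unknown objective {objective!r}")

    def f(v):
        # finite-difference steps may cross the positivity boundary when an
        # estimate sits close to it; treat the outside as zero likelihood
        try:
            val = obj(ParamVector(*v), sample)
        except ValueError:
            return -1e300
        return val if np.isfinite(val) else -1e300

    return -_hessian_fd(f, theta_hat.as_array(), rel_step, richardson)


def asymptotic_ci(theta_hat: ParamVector, sample: TypeICensoredSample,
                  gamma: float = 0.05, objective="mle",
                  rel_step: float = 1e-4, richardson: bool = True) -> CIResult:
    """Wald intervals theta_i +/- z_{1-gamma/2} sqrt(V_ii).

    V is the inverse observed information.  Parameters whose estimated
    variance is non-positive (or whose information matrix is singular)
    are flagged ``ok = False`` and get NaN bounds rather than a bogus
    interval.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - gamma / 2.0)
    info = observed_information(theta_hat, sample, objective, rel_step,
                                richardson)
    est = theta_hat.as_array()
    try:
        V = np.linalg.inv(info)
        var = np.diag(V).copy()
    except np.linalg.LinAlgError:
        var = np.full(3, np.nan)
    ok = np.isfinite(var) & (var > 0)
    se = np.sqrt(np.where(ok, var, np.nan))
    low = est - z * se
    high = est + z * se
    return CIResult(
        low=low, high=high, length=2.0 * z * se, level=1.0 - gamma,
        method="asymptotic-" + (objective if isinstance(objective, str) else "custom"),
        ok=ok,
    )
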