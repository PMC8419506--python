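"""Type-I censored samples and frequentist estimation (MLE, MPS).

A Type-I censored life test puts ``n_total`` units on test and stops at a
fixed time ``T``: the ``m`` failure times at or before ``T`` are observed,
the remaining ``n_total - m`` units are only known to survive past ``T``.
Complete samples are the degenerate case ``T = inf`` (``m = n_total``).

The log-likelihood is ``sum_i log g(x_i) + (n - m) log S(T)`` and the
log-product-of-spacings objective is built from CDF increments between
consecutive order statistics; both are assembled from the distribution
module so there is a single source of truth for the density.
Optimization runs in log-parameter space (positivity for free) with a
Gumbel-moment start for the Frechet part and multi-start fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .distribution import ParamVector, _log1mexp, cdf, logpdf, logsf

__all__ = ["TypeICensoredSample", "FitResult", "loglik", "fit_mle",
           "mps_objective", "fit_mps"]


@dataclass(frozen=True)
class TypeICensoredSample:
    """Ordered observed failure times plus censoring metadata.

    Parameters
    ----------
    times : array-like
        The m observed failure times (any order; stored sorted).
    n_total : int
        Number of units on test, n >= m.
    censor_time : float
        Test termination time T; ``inf`` for a complete sample.
    """

    times: np.ndarray
    n_total: int
    censor_time: float = math.inf

    def __post_init__(self) -> None:
        t = np.sort(np.asarray(self.times, dtype=float).ravel())
        if t.size and not np.all(t > 0):
            raise ValueError("failure times must be strictly positive")
        if not self.censor_time > 0:
            raise ValueError("censor_time must be positive")
        if t.size and t[-1] > self.censor_time:
            raise ValueError("observed times must not exceed the censoring time")
        if self.n_total < t.size:
            raise ValueError(f"n_total={self.n_total} < m={t.size}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_total", int(self.n_total))
        object.__setattr__(self, "censor_time", float(self.censor_time))

    @classmethod
    def complete(cls, times) -> "TypeICensoredSample":
        times = np.asarray(times, dtype=float)
        return cls(times=times, n_total=times.size, censor_time=math.inf)

    @property
    def m(self) -> int:
        """Number of observed failures."""
        return int(self.times.size)

    @property
    def n_censored(self) -> int:
        return self.n_total - self.m

    @property
    def is_complete(self) -> bool:
        return self.m == self.n_total


@dataclass
class FitResult:
    """Point estimate with optimizer diagnostics."""

    theta_hat: ParamVector
    objective: float
    converged: bool
    n_eval: int
    method: str
    covariance: np.ndarray | None = None
    message: str = ""


def loglik(theta, sample: TypeICensoredSample) -> float:
    """Type-I censored log-likelihood (additive constant dropped).

    ``sum_i log g(x_i) + (n - m) log S(T)``; the censoring term vanishes
    for complete samples.  Returns -inf (never NaN) when any density
    factor is zero.
    """
    lp = logpdf(sample.times, theta) if sample.m else np.array([])
    ll = float(np.sum(lp))
    if sample.n_censored > 0:
        ll += sample.n_censored * float(logsf(sample.censor_time, theta))
    return ll if np.isfinite(ll) else -math.inf


def mps_objective(theta, sample: TypeICensoredSample) -> float:
    """Log product-of-spacings objective.

    ``log G(x_1) + sum_{i=2}^m log[G(x_i) - G(x_{i-1})] + log S(x_m)
    + (n - m) log S(T)``.  For a complete sample this is the standard
    (n+1)-spacing form whose exponentiated spacings sum to one.  Any
    zero spacing yields -inf.
    """
    x = sample.times
    if x.size < 1:
        raise ValueError("MPS requires at least one observed failure")
    if np.any(np.diff(x) <= 0):
        raise ValueError("MPS requires strictly increasing times (tied values)")
    G = cdf(x, theta)
    first = G[0]
    diffs = np.diff(G)
    if first <= 0.0 or np.any(diffs <= 0.0):
        return -math.inf
    total = math.log(first) + float(np.sum(np.log(diffs)))
    last = float(logsf(x[-1], theta))
    if not np.isfinite(last):
        return -math.inf
    total += last
    if sample.n_censored > 0:
        total += sample.n_censored * float(logsf(sample.censor_time, theta))
    return total if np.isfinite(total) else -math.inf


# ---------------------------------------------------------------------------
# batched objective evaluation (used by the Newton solver's FD stencils)


def _batch_loglik(thetas: np.ndarray, sample: TypeICensoredSample) -> np.ndarray:
    """Censored log-likelihood at many parameter points at once.

    ``thetas`` is (q, 3) in natural parameter space; returns (q,) with
    -inf wherever the likelihood degenerates.
    """
    a = thetas[:, :1]
    b = thetas[:, 1:2]
    l = thetas[:, 2:3]
    x = sample.times[None, :]
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        t = (a / x) ** l
        F = np.exp(-t)
        omF = -np.expm1(-t)
        lp = (np.log(l) + l * np.log(a) - (l + 1.0) * np.log(x) - t
              + np.log1p(b * omF) - b * F)
        ll = lp.sum(axis=1)
        if sample.n_censored > 0:
            tc = (a[:, 0] / sample.censor_time) ** l[:, 0]
            ll = ll + sample.n_censored * (
                _log1mexp(tc) - b[:, 0] * np.exp(-tc))
    ll[~np.isfinite(ll)] = -np.inf
    return ll


def _batch_mps(thetas: np.ndarray, sample: TypeICensoredSample) -> np.ndarray:
    """Log product-of-spacings at many parameter points at once."""
    a = thetas[:, :1]
    b = thetas[:, 1:2]
    l = thetas[:, 2:3]
    x = sample.times[None, :]
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        t = (a / x) ** l
        F = np.exp(-t)
        lsf = _log1mexp(t) - b * F
        G = -np.expm1(lsf)
        first = G[:, 0]
        diffs = np.diff(G, axis=1)
        bad = (first <= 0) | np.any(diffs <= 0, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            total = np.log(first) + np.sum(np.log(diffs), axis=1) + lsf[:, -1]
        if sample.n_censored > 0:
            tc = (a[:, 0] / sample.censor_time) ** l[:, 0]
            total = total + sample.n_censored * (
                _log1mexp(tc) - b[:, 0] * np.exp(-tc))
    total[bad | ~np.isfinite(total)] = -np.inf
    return total


_BATCH_OBJECTIVES = {"mle": _batch_loglik, "mps": _batch_mps}


def _stencil(z: np.ndarray, h: float) -> np.ndarray:
    """19-point central-difference stencil for gradient + Hessian in 3D."""
    pts = [z]
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        pts += [z + e, z - e]
    for i in range(3):
        for j in range(i + 1, 3):
            ei = np.zeros(3)
            ei[i] = h
            ej = np.zeros(3)
            ej[j] = h
            pts += [z + ei + ej, z + ei - ej, z - ei + ej, z - ei - ej]
    return np.array(pts)


def _grad_hess_from_stencil(f: np.ndarray, h: float):
    g = np.empty(3)
    H = np.empty((3, 3))
    for i in range(3):
        g[i] = (f[1 + 2 * i] - f[2 + 2 * i]) / (2.0 * h)
        H[i, i] = (f[1 + 2 * i] - 2.0 * f[0] + f[2 + 2 * i]) / h**2
    idx = 7
    for i in range(3):
        for j in range(i + 1, 3):
            H[i, j] = H[j, i] = (
                f[idx] - f[idx + 1] - f[idx + 2] + f[idx + 3]
            ) / (4.0 * h * h)
            idx += 4
    return g, H


def fit_newton(sample: TypeICensoredSample, init: ParamVector,
               objective: str = "mle", max_iter: int = 50,
               tol: float = 1e-8, h: float = 1e-5,
               bound: float = 10.0) -> FitResult:
    """Undamped Newton-Raphson on the score equations from ``init``.

    Iterates ``z <- z - H^{-1} g`` on the log parameters with
    finite-difference gradient and Hessian, exactly the classical
    root-solving of the score equations.  The iteration either converges
    quadratically to the stationary point whose basin contains ``init``
    (declared converged only when the Hessian there is negative
    definite, i.e. a genuine local maximum) or diverges — singular
    Hessian, explosive step, or iteration budget — which is reported as
    ``converged=False``.  On ridged multimodal surfaces this is the
    solver that answers "is there a maximum near the start?", in
    contrast to the global search of :func:`fit_mle`.
    """
    if objective not in _BATCH_OBJECTIVES:
        raise ValueError("objective must be 'mle' or 'mps'")
    batch = _BATCH_OBJECTIVES[objective]
    z = np.log(init.as_array())
    n_eval = 0
    for _ in range(max_iter):
        f = batch(np.exp(_stencil(z, h)), sample)
        n_eval += f.size
        if not np.all(np.isfinite(f)):
            break
        g, H = _grad_hess_from_stencil(f, h)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        z_new = z - step
        if not np.all(np.isfinite(z_new)) or np.any(np.abs(z_new) > bound):
            break
        z = z_new
        if np.max(np.abs(step)) < tol:
            if np.all(np.linalg.eigvalsh(H) < 0.0):
                theta = ParamVector(*np.exp(z))
                val = float(batch(np.exp(z)[None, :], sample)[0])
                return FitResult(theta, val, True, n_eval,
                                 "MLE-NR" if objective == "mle" else "MPS-NR")
            break
    theta = ParamVector(*np.exp(np.clip(z, -bound, bound)))
    return FitResult(theta, -math.inf, False, n_eval,
                     "MLE-NR" if objective == "mle" else "MPS-NR",
                     message="Newton iteration did not converge to a local maximum")


# ---------------------------------------------------------------------------
# optimization


def _gumbel_init(sample: TypeICensoredSample) -> np.ndarray:
    """Start values from the Gumbel representation of log X.

    For the Frechet baseline, log X = log alpha - (1/lam) log E with E
    standard exponential, so sd(log X) = pi/(lam sqrt(6)) and
    mean(log X) = log alpha + gamma_E/lam.  Computed on the observed
    failures only (a rough start is all that is needed); beta starts
    at 1.
    """
    ly = np.log(sample.times)
    s = float(np.std(ly))
    lam0 = math.pi / (math.sqrt(6.0) * s) if s > 1e-12 else 1.0
    lam0 = min(max(lam0, 0.05), 50.0)
    alpha0 = math.exp(float(np.mean(ly)) - np.euler_gamma / lam0)
    return np.array([math.log(alpha0), 0.0, math.log(lam0)])


# deterministic multiplicative perturbations for multi-start (log-scale)
_START_OFFSETS = (
    np.zeros(3),
    np.array([0.5, -1.0, 0.3]),
    np.array([-0.5, 1.0, -0.3]),
    np.array([1.0, 0.5, -0.6]),
    np.array([-1.0, -0.5, 0.6]),
)


def _maximize(obj, sample, init, method_name, xatol=1e-6, fatol=1e-8,
              n_starts=5) -> FitResult:
    """Nelder-Mead in log-parameter space with multi-start fallback."""

    def neg(z):
        if np.any(np.abs(z) > 60.0):  # absurd magnitudes: reject
            return math.inf
        v = obj(ParamVector(*np.exp(z)), sample)
        return -v if np.isfinite(v) else math.inf

    z0_base = np.log(init.as_array()) if init is not None else _gumbel_init(sample)
    best = None
    n_eval = 0
    for trial, off in enumerate(_START_OFFSETS[:n_starts]):
        z0 = z0_base + off
        res = optimize.minimize(
            neg, z0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 2000},
        )
        n_eval += res.nfev
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            if trial == 0 or best.fun == res.fun:
                break
    theta = ParamVector(*np.exp(best.x))
    return FitResult(
        theta_hat=theta,
        objective=-float(best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
        n_eval=n_eval,
        method=method_name,
        message=str(best.message),
    )


def _maximize_local(obj, sample, init: ParamVector, method_name: str,
                    gtol: float = 1e-6, grad_ok: float = 0.1) -> FitResult:
    """Single quasi-Newton (BFGS) ascent in log-parameter space.

    Newton-type iteration from a caller-supplied start: converges to the
    stationary point in whose basin the start lies rather than hunting
    for a global optimum.  Convergence is judged by the gradient
    sup-norm at the returned point (BFGS's own "precision loss" flag is
    routinely raised at perfectly good optima on ridged surfaces).
    """

    def neg(z):
        if np.any(np.abs(z) > 60.0):
            return math.inf
        v = obj(ParamVector(*np.exp(z)), sample)
        return -v if np.isfinite(v) else math.inf

    z0 = np.log(init.as_array())
    res = optimize.minimize(neg, z0, method="BFGS",
                            options={"maxiter": 300, "gtol": gtol})
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else math.inf
    ok = bool(np.isfinite(res.fun) and np.all(np.isfinite(res.x))
              and gnorm < grad_ok)
    return FitResult(
        theta_hat=ParamVector(*np.exp(res.x)),
        objective=-float(res.fun),
        converged=ok,
        n_eval=res.nfev,
        method=method_name,
        message=str(res.message),
    )


def fit_mle(sample: TypeICensoredSample, init: ParamVector | None = None,
            options: dict | None = None, local: bool = False) -> FitResult:
    """Maximum-likelihood fit of (alpha, beta, lam).

    By default a simplex search on the log parameters with multi-start:
    the first start comes from a Gumbel-moment fit of the Frechet part
    with ``beta = 1``, and up to four deterministic perturbed restarts
    are tried on failure.  With ``local=True`` (requires ``init``) a
    single quasi-Newton ascent from ``init`` is performed instead — the
    Newton-type protocol used by the Monte-Carlo harness, which keeps
    the estimate in the basin of the supplied start on multimodal
    likelihood surfaces.  Non-convergence is reported in the result,
    never raised.
    """
    if sample.m < 3:
        raise ValueError("need at least 3 observed failures for a 3-parameter fit")
    if local:
        if init is None:
            raise ValueError("local=True requires an explicit init")
        return _maximize_local(loglik, sample, init, "MLE")
    opts = options or {}
    return _maximize(loglik, sample, init, "MLE", **opts)


def fit_mps(sample: TypeICensoredSample, init: ParamVector | None = None,
            options: dict | None = None, local: bool = False) -> FitResult:
    """Maximum-product-of-spacings fit of (alpha, beta, lam).

    Same optimization contract as :func:`fit_mle` (including the
    ``local`` Newton-type mode).  Tied observations are perturbed by the
    smallest representable jitter (with a warning) so that spacings are
    strictly positive.
    """
    if sample.m < 3:
        raise ValueError("need at least 3 observed failures for a 3-parameter fit")
    work = sample
    if np.any(np.diff(sample.times) <= 0):
        warnings.warn("tied failure times jittered for MPS", stacklevel=2)
        jit = np.cumsum(np.where(np.diff(sample.times, prepend=0.0) <= 0, 1, 0))
        times = sample.times * (1.0 + 1e-12 * jit)
        work = TypeICensoredSample(times, sample.n_total, sample.censor_time)
    if local:
        if init is None:
            raise ValueError("local=True requires an explicit init")
        return _maximize_local(mps_objective, work, init, "MPS")
    opts = options or {}
    return _maximize(mps_objective, work, init, "MPS", **opts)
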