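"""The NEX-Frechet (NEXF) lifetime distribution.

The NEX ("new exponential-X") family maps a baseline CDF ``F`` into

.. math::

    G(x) = 1 - (1 - F(x))\\,e^{-\\beta F(x)},  \\qquad \\beta > 0,

which preserves the support of the baseline while bending its hazard into
increasing, decreasing or bathtub shapes.  With the heavy-tailed Frechet
baseline

.. math::

    F(x) = \\exp(-(\\alpha/x)^\\lambda), \\qquad x > 0,

one obtains a three-parameter lifetime law, NEXF(alpha, beta, lam), whose
density is

.. math::

    g(x) = f(x)\\,(1 + \\beta(1 - F(x)))\\,e^{-\\beta F(x)},

with ``f`` the Frechet density.  ``alpha`` is a scale in time units,
``lam`` controls the right tail (moments of order ``r`` exist iff
``r < lam``), and ``beta`` is the family shape; ``beta -> 0`` recovers the
plain Frechet distribution.  ``lam = 2`` gives the NEX inverse-Rayleigh
special case.

This module is the single source of truth for all distribution functions:
densities, survival quantities, the Lambert-W quantile, random variates,
the linear (series) representation, moments and incomplete moments,
reliability functionals (mean residual life / mean inactivity time),
inequality curves, and order statistics.  Everything is computed in
log-space where overflow is possible, so extreme arguments yield exact
0/1 limits rather than NaN.

The moment generating function is intentionally absent: for a heavy-tailed
baseline the formal series diverges for every t > 0, so no finite MGF
exists to compute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "ParamVector",
    "SeriesExpansion",
    "MomentDoesNotExistError",
    "cdf",
    "pdf",
    "logpdf",
    "sf",
    "logsf",
    "hazard",
    "reversed_hazard",
    "quantile",
    "rvs",
    "series_coefficients",
    "raw_moment",
    "central_moments_and_cumulants",
    "incomplete_moment",
    "mrl",
    "mit",
    "lorenz",
    "bonferroni",
    "zenga",
    "order_stat_pdf",
    "order_stat_cdf",
]

_EULER_GAMMA = float(np.euler_gamma)


class MomentDoesNotExistError(ValueError):
    """A moment of order ``r >= lam`` was requested.

    The Frechet right tail decays like ``x**(-lam-1)``, so ``E[X**r]``
    is infinite for ``r >= lam``; the condition is signalled explicitly
    rather than returned as ``inf``/NaN.
    """


@dataclass(frozen=True)
class ParamVector:
    """Parameter triple of the NEXF distribution.

    Parameters
    ----------
    alpha : float
        Frechet scale, in the same units as the time variable.  > 0.
    beta : float
        NEX family shape, dimensionless.  > 0; ``beta = 0`` is admitted
        as the limiting plain-Frechet reference.
    lam : float
        Frechet tail shape, dimensionless.  > 0.  Moments of order
        ``r`` exist only for ``r < lam``.
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        a, b, l = float(self.alpha), float(self.beta), float(self.lam)
        if not (math.isfinite(a) and math.isfinite(b) and math.isfinite(l)):
            raise ValueError(f"parameters must be finite, got {(a, b, l)}")
        if not (a > 0 and l > 0 and b >= 0):
            raise ValueError(
                f"require alpha > 0, beta >= 0, lam > 0, got {(a, b, l)}"
            )
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "lam", l)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.lam])


def _unpack(theta) -> tuple[float, float, float]:
    """Validate and unpack a ParamVector or (alpha, beta, lam) triple."""
    if isinstance(theta, ParamVector):
        return theta.alpha, theta.beta, theta.lam
    a, b, l = (float(v) for v in theta)
    return ParamVector(a, b, l).alpha, b, l


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if x.size and not np.all(x > 0):
        raise ValueError("x must be strictly positive")
    return x


def _tpow(x, a, l):
    """(alpha/x)**lam, overflow-safe (returns inf for tiny x)."""
    with np.errstate(over="ignore"):
        return (a / x) ** l


_LOG2 = math.log(2.0)


def _log1mexp(t):
    """log(1 - exp(-t)) for t > 0, accurate in both regimes.

    Uses log(-expm1(-t)) for t < log 2 and log1p(-exp(-t)) beyond, the
    standard split that avoids catastrophic loss when exp(-t) is tiny.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        small = np.log(-np.expm1(-np.minimum(t, _LOG2)))
        large = np.log1p(-np.exp(-np.maximum(t, _LOG2)))
    return np.where(t < _LOG2, small, large)


# ---------------------------------------------------------------------------
# distribution functions


def logsf(x, theta):
    """Log survival function, exact in both tails."""
    a, b, l = _unpack(theta)
    x = _check_x(x)
    t = _tpow(x, a, l)
    F = np.exp(-t)
    # log(1 - F) = log(1 - e^{-t}) via the two-regime form
    return _log1mexp(t) - b * F


def sf(x, theta):
    """Survival function S(x) = (1 - F(x)) exp(-beta F(x))."""
    return np.exp(logsf(x, theta))


def cdf(x, theta):
    """CDF G(x) = 1 - (1 - F(x)) exp(-beta F(x)), F Frechet."""
    return -np.expm1(logsf(x, theta))


def _logcdf(x, theta):
    ls = logsf(x, theta)
    with np.errstate(divide="ignore"):
        return np.log(-np.expm1(ls))


def logpdf(x, theta):
    """Log density; -inf (never NaN) where the density vanishes."""
    a, b, l = _unpack(theta)
    x = _check_x(x)
    t = _tpow(x, a, l)
    F = np.exp(-t)
    omF = -np.expm1(-t)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            np.log(l)
            + l * np.log(a)
            - (l + 1.0) * np.log(x)
            - t
            + np.log1p(b * omF)
            - b * F
        )
    # t = inf (x -> 0) gives -inf + finite = -inf already; guard any stray NaN
    return np.where(np.isnan(out), -np.inf, out)


def pdf(x, theta):
    """Density g(x) = f(x) (1 + beta (1 - F(x))) exp(-beta F(x))."""
    return np.exp(logpdf(x, theta))


def hazard(x, theta):
    """Hazard rate g/S.

    The exp(-beta F) factors of density and survival cancel, leaving the
    closed form ``f (1 + beta (1-F)) / (1-F)`` which is evaluated in
    log-space (numerically stabler than the literal ratio pdf/sf).
    """
    a, b, l = _unpack(theta)
    x = _check_x(x)
    t = _tpow(x, a, l)
    omF = -np.expm1(-t)
    with np.errstate(divide="ignore"):
        lh = (
            np.log(l)
            + l * np.log(a)
            - (l + 1.0) * np.log(x)
            - t
            + np.log1p(b * omF)
            - _log1mexp(t)
        )
    with np.errstate(over="ignore"):
        return np.exp(lh)


def reversed_hazard(x, theta):
    """Reversed hazard rate g/G."""
    with np.errstate(over="ignore"):
        return np.exp(logpdf(x, theta) - _logcdf(x, theta))


def quantile(p, theta):
    """Quantile function via the principal Lambert-W branch.

    Solving ``G(x) = p`` reduces to ``(1-u) e^{-beta u} = 1-p`` for
    ``u = F(x)``, whence ``u = 1 - W(beta (1-p) e^beta) / beta``.  The
    W argument is positive, so the principal branch is single-valued and
    real; it is evaluated as ``wrightomega(beta + log(beta(1-p)))``,
    which never overflows even for large ``beta``.  Then
    ``x = alpha (-log u)^{-1/lam}`` (the Frechet quantile of ``u``).
    """
    a, b, l = _unpack(theta)
    p = np.asarray(p, dtype=float)
    if p.size and not (np.all(p > 0.0) and np.all(p < 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if b == 0.0:
        u = p
    else:
        w = b + np.log(b) + np.log1p(-p)
        u = 1.0 + (-special.wrightomega(w).real / b)
        # round-off can push u onto the boundary of (0,1); clamp inward
        tiny = np.finfo(float).tiny
        u = np.clip(u, tiny, 1.0 - np.finfo(float).epsneg)
    return a * (-np.log(u)) ** (-1.0 / l)


def rvs(n, theta, seed=None, rng=None):
    """Draw ``n`` i.i.d. variates by inverse-transform sampling.

    Exactly reproducible for a fixed ``seed`` (or caller-supplied
    ``rng``); the only source of randomness is one uniform vector.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(int(n))
    # keep u away from exact 0 (rng.random is in [0,1))
    u = np.maximum(u, np.finfo(float).tiny)
    return quantile(u, theta)


# ---------------------------------------------------------------------------
# linear representation


@dataclass(frozen=True)
class SeriesExpansion:
    """Truncated linear representation of the NEXF density.

    Expanding ``exp(-beta F)`` gives

    ``g(x) = sum_{m=0,1} sum_{k>=0} phi_{m,k} h_{m+k}(x)``

    where ``phi_{m,k} = (-1)^{m+k+1} beta^k / k!`` and ``h_j`` is the
    Frechet density with scale ``alpha j^{1/lam}`` and shape ``lam``
    (``h_0`` is the point mass at 0 and contributes nothing on x > 0).
    Coefficients are attached to their component scales so the expansion
    can be evaluated or integrated term by term.
    """

    m: np.ndarray
    k: np.ndarray
    phi: np.ndarray
    scale: np.ndarray
    truncation_K: int
    theta: ParamVector

    @property
    def order(self) -> np.ndarray:
        """Component order j = m + k (scale of the j-fold power F^j)."""
        return self.m + self.k

    def pdf(self, x) -> np.ndarray:
        """Evaluate the truncated series density at x (> 0)."""
        x = _check_x(np.atleast_1d(x))
        l = self.theta.lam
        total = np.zeros_like(x)
        for phi, s in zip(self.phi, self.scale):
            if s == 0.0:
                continue
            t = _tpow(x, s, l)
            with np.errstate(divide="ignore"):
                total += phi * np.exp(
                    np.log(l) + l * np.log(s) - (l + 1.0) * np.log(x) - t
                )
        return total


def _tail_ok(b: float, K: int, tol: float = 1e-8) -> bool:
    """True when the dropped series tail is provably below ``tol``."""
    # terms beyond K are bounded by 2 * b^(K+1)/(K+1)! * (geometric tail)
    lead = (K + 1) * math.log(b) - special.gammaln(K + 2) if b > 0 else -np.inf
    if b > (K + 1) / 2:  # geometric ratio not yet < 1/2; be conservative
        return False
    return lead < math.log(tol) - math.log(4.0)


def series_coefficients(theta, K: int = 40, tail_tol: float = 1e-12) -> SeriesExpansion:
    """Coefficients ``phi_{m,k}`` of the linear representation.

    ``K`` truncates the inner sum over ``k``; trailing terms with
    ``beta^k/k! < tail_tol`` are dropped (they cannot affect the density
    beyond that magnitude).  The sign convention
    ``phi_{m,k} = (-1)^{m+k+1} beta^k / k!`` is the one under which the
    expanded density reproduces the exact one.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    a, b, l = _unpack(theta)
    ks = np.arange(K + 1)
    with np.errstate(divide="ignore"):
        logmag = np.where(ks == 0, 0.0, ks * np.log(b) if b > 0 else -np.inf)
    logmag = logmag - special.gammaln(ks + 1)
    mag = np.exp(logmag)
    keep_upto = int(np.max(np.nonzero(mag >= tail_tol)[0], initial=0))
    ks = ks[: keep_upto + 1]
    mag = mag[: keep_upto + 1]

    m = np.repeat([0, 1], ks.size)
    k = np.tile(ks, 2)
    phi = ((-1.0) ** (m + k + 1)) * np.tile(mag, 2)
    order = m + k
    scale = a * np.where(order > 0, order, 1.0) ** (1.0 / l)
    scale = np.where(order > 0, scale, 0.0)
    return SeriesExpansion(
        m=m, k=k, phi=phi, scale=scale, truncation_K=K,
        theta=ParamVector(a, b, l),
    )


# ---------------------------------------------------------------------------
# moments and moment-based functionals


def _moment_quad(r: float, theta, upper_p: float = 1.0) -> float:
    """E[X^r 1{X <= Q(upper_p)}] via the probability-scale integral
    ``int_0^{upper_p} Q(p)^r dp`` (robust for heavy tails)."""
    val, _ = integrate.quad(
        lambda p: float(quantile(p, theta)) ** r, 0.0, upper_p,
        limit=200, epsabs=1e-11, epsrel=1e-11,
    )
    return val


def raw_moment(r: float, theta, K: int = 40) -> float:
    """Raw moment E[X^r], r < lam (else MomentDoesNotExistError).

    Computed from the series representation,
    ``sum phi_{m,k} Gamma(1 - r/lam) (alpha (m+k)^{1/lam})^r``,
    with an adaptive-quadrature fallback whenever the truncated tail of
    the series cannot be certified below 1e-8 (large beta).
    """
    a, b, l = _unpack(theta)
    if r >= l:
        raise MomentDoesNotExistError(
            f"E[X^{r}] is infinite for lam = {l} (requires r < lam)"
        )
    if r == 0:
        return 1.0
    if b == 0.0:
        return a**r * special.gamma(1.0 - r / l)
    if not _tail_ok(b, K):
        return _moment_quad(r, theta)
    se = series_coefficients(theta, K)
    mask = se.order > 0
    g = special.gamma(1.0 - r / l)
    return float(np.sum(se.phi[mask] * g * se.scale[mask] ** r))


def incomplete_moment(s: float, t: float, theta, K: int = 40) -> float:
    """Lower incomplete moment Psi_s(t) = int_0^t x^s g(x) dx, s < lam.

    Termwise each Frechet component integrates to an *upper* incomplete
    gamma function, ``scale^s Gamma(1 - s/lam, (m+k)(alpha/t)^lam)``
    (the Frechet substitution y = (scale/x)^lam maps (0, t] onto
    [(scale/t)^lam, inf)).  ``t = inf`` returns the full raw moment.
    """
    a, b, l = _unpack(theta)
    if s >= l:
        raise MomentDoesNotExistError(
            f"incomplete moment of order {s} requires s < lam = {l}"
        )
    if not t > 0:
        raise ValueError("t must be positive")
    if np.isinf(t):
        return raw_moment(s, theta, K)
    if b > 0 and not _tail_ok(b, K):
        return _moment_quad(s, theta, upper_p=float(cdf(t, theta)))
    se = series_coefficients(theta, K)
    mask = se.order > 0
    aa = 1.0 - s / l
    z = se.order[mask] * (a / t) ** l
    g = special.gamma(aa) * special.gammaincc(aa, z)
    if b == 0.0:
        # series degenerates to the single baseline term
        return float(a**s * special.gamma(aa) * special.gammaincc(aa, (a / t) ** l))
    return float(np.sum(se.phi[mask] * se.scale[mask] ** s * g))


def central_moments_and_cumulants(n_max: int, theta, K: int = 40):
    """Central moments mu_1..mu_{n_max} and cumulants kappa_1..kappa_{n_max}.

    Central moments come from the binomial recombination of raw moments;
    cumulants from the standard recursion
    ``kappa_n = mu'_n - sum_{j=1}^{n-1} C(n-1, j-1) kappa_j mu'_{n-j}``.
    Requires ``n_max < lam``.
    """
    a, b, l = _unpack(theta)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if n_max >= l:
        raise MomentDoesNotExistError(
            f"moments up to order {n_max} require n_max < lam = {l}"
        )
    raw = [1.0] + [raw_moment(r, theta, K) for r in range(1, n_max + 1)]
    mu1 = raw[1]
    central = []
    for n in range(1, n_max + 1):
        c = sum(
            math.comb(n, j) * (-mu1) ** j * raw[n - j] for j in range(0, n + 1)
        )
        central.append(float(c))
    kappa: list[float] = []
    for n in range(1, n_max + 1):
        k_n = raw[n] - sum(
            math.comb(n - 1, j - 1) * kappa[j - 1] * raw[n - j]
            for j in range(1, n)
        )
        kappa.append(float(k_n))
    return central, kappa


def mrl(t: float, theta, K: int = 40) -> float:
    """Mean residual life E[X - t | X > t] = (mu - Psi_1(t))/S(t) - t."""
    a, b, l = _unpack(theta)
    if l <= 1:
        raise MomentDoesNotExistError("MRL requires a finite mean (lam > 1)")
    if not t > 0:
        raise ValueError("t must be positive")
    mu = raw_moment(1.0, theta, K)
    psi = incomplete_moment(1.0, t, theta, K)
    s = float(sf(t, theta))
    if s == 0.0:
        raise ValueError("survival underflows to 0 at this t")
    return (mu - psi) / s - t


def mit(t: float, theta, K: int = 40) -> float:
    """Mean inactivity time E[t - X | X <= t] = t - Psi_1(t)/G(t)."""
    a, b, l = _unpack(theta)
    if l <= 1:
        raise MomentDoesNotExistError("MIT requires a finite mean (lam > 1)")
    if not t > 0:
        raise ValueError("t must be positive")
    G = float(cdf(t, theta))
    if G == 0.0:
        return 0.0
    return t - incomplete_moment(1.0, t, theta, K) / G


def lorenz(p: float, theta, K: int = 40) -> float:
    """Lorenz curve L(p) = Psi_1(Q(p)) / mu, 0 < p < 1 (lam > 1)."""
    a, b, l = _unpack(theta)
    if l <= 1:
        raise MomentDoesNotExistError("Lorenz curve requires lam > 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    xp = float(quantile(p, theta))
    return incomplete_moment(1.0, xp, theta, K) / raw_moment(1.0, theta, K)


def bonferroni(p: float, theta, K: int = 40) -> float:
    """Bonferroni curve B(p) = L(p)/p."""
    return lorenz(p, theta, K) / p


def zenga(p: float, theta, K: int = 40) -> float:
    """Zenga curve Z(p) = (L(p) - p) / (p (1 - L(p)))."""
    L = lorenz(p, theta, K)
    return (L - p) / (p * (1.0 - L))


# ---------------------------------------------------------------------------
# order statistics


def _check_order(i: int, n: int) -> None:
    if not (isinstance(i, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("i and n must be integers")
    if not 1 <= i <= n:
        raise ValueError(f"require 1 <= i <= n, got i={i}, n={n}")


def order_stat_pdf(i: int, n: int, x, theta):
    """Density of the i-th order statistic of an n-sample.

    Uses the beta-binomial form
    ``n!/((i-1)!(n-i)!) G^{i-1} (1-G)^{n-i} g`` in log-space; this is
    algebraically identical to (and numerically better than) the 2F1
    closed form sometimes quoted for this family.
    """
    _check_order(i, n)
    lg = _logcdf(x, theta)
    ls = logsf(x, theta)
    lp = logpdf(x, theta)
    lc = (
        special.gammaln(n + 1)
        - special.gammaln(i)
        - special.gammaln(n - i + 1)
    )
    with np.errstate(invalid="ignore"):
        out = np.exp(lc + (i - 1) * lg + (n - i) * ls + lp)
    return np.where(np.isnan(out), 0.0, out)


def order_stat_cdf(i: int, n: int, x, theta):
    """CDF of the i-th order statistic: regularized incomplete beta
    I_G(i, n-i+1) = sum_{r=i}^n C(n,r) G^r (1-G)^{n-r}."""
    _check_order(i, n)
    G = cdf(x, theta)
    return special.betainc(i, n - i + 1, G)
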