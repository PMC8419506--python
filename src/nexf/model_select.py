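"""Censored-data model selection: information criteria and modified KS.

Fits the NEXF model and its competitors (exponential, two- and
three-parameter Frechet) to a possibly Type-I censored sample under the
shared censored-likelihood skeleton ``sum log f(x_i) + (n-m) log S(T)``,
computes AIC / CAIC / BIC / HQIC, and assesses fit with a modified
Kolmogorov-Smirnov statistic for Type-I censored data: the empirical
CDF on the full n-unit scale is compared to the fitted CDF over the
observed failures only (everything past T is unobservable), and the
null distribution of the statistic is obtained by parametric bootstrap
(simulate from the fitted model at the same n and T, refit, recompute).
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .censored import TypeICensoredSample, fit_mle
from .distribution import (ParamVector, _log1mexp, cdf as nexf_cdf,
                           quantile as nexf_quantile)

__all__ = ["CandidateModel", "ModelComparison", "info_criteria",
           "fit_competitor", "censored_ks", "compare_models", "MODEL_NAMES"]

InfoCriteria = namedtuple("InfoCriteria", ["aic", "caic", "bic", "hqic"])

MODEL_NAMES = ("NEXF", "Exponential", "Frechet2", "Frechet3")


def info_criteria(loglik: float, k: int, n: int) -> InfoCriteria:
    """AIC = 2k - 2l; CAIC = 2nk/(n-k-1) - 2l; BIC = k log n - 2l;
    HQIC = 2k log(log n) - 2l.

    ``n`` is the number of units on test (not just observed failures).
    CAIC is undefined for n <= k + 1 and raises.
    """
    if n <= k + 1:
        raise ValueError(f"CAIC undefined for n={n} <= k+1={k + 1}")
    m2l = -2.0 * loglik
    return InfoCriteria(
        aic=2.0 * k + m2l,
        caic=2.0 * n * k / (n - k - 1.0) + m2l,
        bic=k * math.log(n) + m2l,
        hqic=2.0 * k * math.log(math.log(n)) + m2l,
    )


@dataclass
class CandidateModel:
    """A fitted candidate lifetime model."""

    name: str
    k: int
    params: dict
    loglik: float
    converged: bool

    def cdf(self, x):
        return _CDFS[self.name](np.asarray(x, dtype=float), self.params)

    def quantile(self, p):
        return _QUANTILES[self.name](np.asarray(p, dtype=float), self.params)

    def rvs(self, n: int, rng) -> np.ndarray:
        u = np.maximum(rng.random(int(n)), np.finfo(float).tiny)
        return self.quantile(u)


@dataclass
class ModelComparison:
    """Criteria / KS table for the surviving candidates."""

    table: pd.DataFrame
    models: dict
    failures: dict

    @property
    def best(self) -> str:
        """Headline winner: smallest AIC (all criteria are reported)."""
        return str(self.table["aic"].idxmin())


# ---------------------------------------------------------------------------
# candidate families: cdf / logpdf / logsf / quantile, textbook forms


def _exp_cdf(x, p):
    return -np.expm1(-p["rate"] * x)


def _exp_quantile(u, p):
    return -np.log1p(-u) / p["rate"]


def _frechet2_cdf(x, p):
    with np.errstate(over="ignore"):
        return np.exp(-((p["alpha"] / x) ** p["lam"]))


def _frechet2_quantile(u, p):
    return p["alpha"] * (-np.log(u)) ** (-1.0 / p["lam"])


def _frechet3_cdf(x, p):
    z = x - p["mu"]
    out = np.zeros_like(np.asarray(z, dtype=float))
    pos = z > 0
    with np.errstate(over="ignore"):
        out[pos] = np.exp(-((np.asarray(z)[pos] / p["scale"]) ** (-p["shape"])))
    return out


def _frechet3_quantile(u, p):
    return p["mu"] + p["scale"] * (-np.log(u)) ** (-1.0 / p["shape"])


def _nexf_cdf(x, p):
    return nexf_cdf(x, p["theta"])


def _nexf_quantile(u, p):
    return nexf_quantile(u, p["theta"])


_CDFS = {"NEXF": _nexf_cdf, "Exponential": _exp_cdf,
         "Frechet2": _frechet2_cdf, "Frechet3": _frechet3_cdf}
_QUANTILES = {"NEXF": _nexf_quantile, "Exponential": _exp_quantile,
              "Frechet2": _frechet2_quantile, "Frechet3": _frechet3_quantile}


def _censored_ll(logpdf_vals: np.ndarray, logsf_T: float,
                 sample: TypeICensoredSample) -> float:
    ll = float(np.sum(logpdf_vals))
    if sample.n_censored > 0:
        ll += sample.n_censored * logsf_T
    return ll if np.isfinite(ll) else -math.inf


def _fit_exponential(sample: TypeICensoredSample) -> CandidateModel:
    # censored-sample MLE in closed form: total time on test
    x = sample.times
    ttot = float(np.sum(x))
    if sample.n_censored > 0:
        ttot += sample.n_censored * sample.censor_time
    rate = sample.m / ttot
    ll = sample.m * math.log(rate) - rate * ttot
    return CandidateModel("Exponential", 1, {"rate": rate}, ll, True)


def _frechet2_ll(a: float, l: float, sample: TypeICensoredSample) -> float:
    x = sample.times
    with np.errstate(over="ignore", divide="ignore"):
        t = (a / x) ** l
        lp = np.log(l) + l * math.log(a) - (l + 1.0) * np.log(x) - t
        lsf = float(_log1mexp((a / sample.censor_time) ** l)) \
            if np.isfinite(sample.censor_time) else 0.0
    return _censored_ll(lp, lsf, sample)


def _fit_frechet2(sample: TypeICensoredSample) -> CandidateModel:
    ly = np.log(sample.times)
    s = max(float(np.std(ly)), 1e-6)
    l0 = min(max(math.pi / (math.sqrt(6.0) * s), 0.05), 50.0)
    a0 = math.exp(float(np.mean(ly)) - np.euler_gamma / l0)

    def neg(z):
        if np.any(np.abs(z) > 60):
            return math.inf
        v = _frechet2_ll(math.exp(z[0]), math.exp(z[1]), sample)
        return -v if np.isfinite(v) else math.inf

    res = optimize.minimize(neg, [math.log(a0), math.log(l0)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8})
    a, l = np.exp(res.x)
    return CandidateModel("Frechet2", 2, {"alpha": float(a), "lam": float(l)},
                          -float(res.fun), bool(res.success))


def _frechet3_ll(shape: float, scale: float, mu: float,
                 sample: TypeICensoredSample) -> float:
    z = sample.times - mu
    if np.any(z <= 0):
        return -math.inf
    with np.errstate(over="ignore", divide="ignore"):
        t = (z / scale) ** (-shape)
        lp = (math.log(shape) - math.log(scale)
              - (shape + 1.0) * (np.log(z) - math.log(scale)) - t)
        if np.isfinite(sample.censor_time):
            tc = ((sample.censor_time - mu) / scale) ** (-shape)
            lsf = float(_log1mexp(tc))
        else:
            lsf = 0.0
    return _censored_ll(lp, lsf, sample)


def _fit_frechet3(sample: TypeICensoredSample) -> CandidateModel:
    xmin = float(sample.times.min())
    ly = np.log(sample.times)
    s = max(float(np.std(ly)), 1e-6)
    sh0 = min(max(math.pi / (math.sqrt(6.0) * s), 0.05), 50.0)
    sc0 = math.exp(float(np.mean(ly)) - np.euler_gamma / sh0)

    # mu parametrized as xmin - exp(z3): the support constraint mu < min(x)
    # holds throughout the unconstrained search
    def neg(z):
        if np.any(np.abs(z) > 60):
            return math.inf
        mu = xmin - math.exp(z[2])
        v = _frechet3_ll(math.exp(z[0]), math.exp(z[1]), mu, sample)
        return -v if np.isfinite(v) else math.inf

    z0 = [math.log(sh0), math.log(sc0), math.log(max(xmin / 2.0, 1e-6))]
    res = optimize.minimize(neg, z0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 3000})
    sh, sc = np.exp(res.x[:2])
    mu = xmin - math.exp(res.x[2])
    return CandidateModel(
        "Frechet3", 3,
        {"shape": float(sh), "scale": float(sc), "mu": float(mu)},
        -float(res.fun), bool(res.success))


def _fit_nexf(sample: TypeICensoredSample) -> CandidateModel:
    res = fit_mle(sample)
    return CandidateModel("NEXF", 3, {"theta": res.theta_hat},
                          res.objective, res.converged)


_FITTERS = {"NEXF": _fit_nexf, "Exponential": _fit_exponential,
            "Frechet2": _fit_frechet2, "Frechet3": _fit_frechet3}


def fit_competitor(name: str, sample: TypeICensoredSample) -> CandidateModel:
    """MLE of one candidate family under the censored-likelihood skeleton.

    Exponential uses the closed-form total-time-on-test estimator; the
    Frechet families are fitted by simplex search in transformed
    parameter space (the three-parameter location is kept strictly below
    the smallest observation by construction).
    """
    if name not in _FITTERS:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return _FITTERS[name](sample)


def ks_statistic(sample: TypeICensoredSample, fitted_cdf) -> float:
    """Modified KS distance for Type-I censored data.

    ``D = max_i max(|i/n - G(x_(i))|, |G(x_(i)) - (i-1)/n|)`` over the
    observed failures, with the empirical CDF on the n-unit scale so the
    censored mass past T is handled correctly.
    """
    m, n = sample.m, sample.n_total
    if m < 1:
        raise ValueError("no observed failures")
    i = np.arange(1, m + 1)
    G = np.asarray(fitted_cdf(sample.times), dtype=float)
    return float(np.max(np.maximum(i / n - G, G - (i - 1) / n)))


def censored_ks(sample: TypeICensoredSample, model: CandidateModel,
                n_boot: int = 1000, seed=None, min_m: int = 5):
    """Modified KS statistic with a parametric-bootstrap p-value.

    Simulates ``n_boot`` Type-I censored samples of the same n and T
    from the fitted model, refits the same family to each, recomputes D,
    and reports ``p = (1 + #{D_b >= D_obs}) / (n_boot + 1)``.  Bootstrap
    replicates with non-convergent refits (or fewer than ``min_m``
    observed failures) are dropped and counted.
    """
    if sample.m < min_m:
        raise ValueError(f"need at least {min_m} observed failures")
    d_obs = ks_statistic(sample, model.cdf)
    if n_boot <= 0:
        return d_obs, math.nan, 0
    rng = np.random.default_rng(seed)
    n, T = sample.n_total, sample.censor_time
    d_boot = []
    n_failed = 0
    for _ in range(n_boot):
        x = model.rvs(n, rng)
        obs = x[x <= T]
        if obs.size < min_m:
            n_failed += 1
            continue
        bsamp = TypeICensoredSample(obs, n, T)
        try:
            refit = _FITTERS[model.name](bsamp)
        except ValueError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        d_boot.append(ks_statistic(bsamp, refit.cdf))
    d_boot = np.asarray(d_boot)
    p = (1.0 + np.sum(d_boot >= d_obs)) / (d_boot.size + 1.0)
    return d_obs, float(p), n_failed


def compare_models(sample: TypeICensoredSample, candidates=MODEL_NAMES,
                   n_boot: int = 0, seed=None) -> ModelComparison:
    """Fit every candidate and assemble the criteria / KS table.

    Per-model fit failures are recorded and the comparison proceeds on
    the survivors; the smallest value of each criterion marks the
    headline model.  ``n_boot = 0`` skips the bootstrap p-values.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    rows = {}
    models = {}
    failures = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(candidates))
    for name, child in zip(candidates, child_seeds):
        try:
            model = fit_competitor(name, sample)
            if not model.converged:
                raise RuntimeError("fit did not converge")
            crit = info_criteria(model.loglik, model.k, sample.n_total)
            d, p, _ = censored_ks(sample, model, n_boot=n_boot, seed=child)
            rows[name] = {
                "k": model.k, "loglik": model.loglik,
                "aic": crit.aic, "caic": crit.caic,
                "bic": crit.bic, "hqic": crit.hqic,
                "ks": d, "p_value": p,
            }
            models[name] = model
        except (ValueError, RuntimeError, FloatingPointError) as exc:
            failures[name] = str(exc)
    if not rows:
        raise RuntimeError(f"all candidate fits failed: {failures}")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "model"
    return ModelComparison(table=table, models=models, failures=failures)
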