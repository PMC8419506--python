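# nexf

Inference toolkit for the **NEX-Fréchet (NEXF) lifetime distribution** —
a three-parameter survival model for positive failure times with
non-monotone (decreasing, upside-down, or near-constant) hazard rates,
aimed at reliability and biomedical duration data observed under
**Type-I censoring** (a trial stopped at a fixed time *T*, with the
units still alive at *T* contributing only their count).

## The model

The NEX family bends a baseline CDF *F* into

```
G(x) = 1 − (1 − F(x)) e^{−β F(x)},          β > 0,
```

and NEXF takes the heavy-tailed Fréchet baseline
`F(x) = exp(−(α/x)^λ)` on `x > 0`, giving the density

```
g(x) = f(x) (1 + β(1 − F(x))) e^{−β F(x)},
```

with `f` the Fréchet density. `α` is a scale (time units), `λ` the
Fréchet tail shape (moments of order `r` exist iff `r < λ`), `β` the
family shape; `β → 0` recovers the plain Fréchet law and `λ = 2` gives
the NEX inverse-Rayleigh special case. The quantile function is closed
form through the principal branch of the Lambert W function, so random
variates come from a one-line inverse transform.

The package provides:

- **distribution** — cdf/pdf/sf/hazard, Lambert-W quantiles, random
  variates, the series (linear) representation, raw/central moments and
  cumulants, incomplete moments, mean residual life / mean inactivity
  time, Lorenz–Bonferroni–Zenga curves, order statistics;
- **censored** — the `TypeICensoredSample` data model, the censored
  log-likelihood `Σ log g(xᵢ) + (n−m) log S(T)`, the maximum-product-
  of-spacings (MPS) objective, and three fitting protocols (multi-start
  global search, truth-initialized quasi-Newton, classical
  Newton–Raphson on the score);
- **bayes** — independent gamma priors, random-walk Metropolis–Hastings
  on log parameters, squared-error-loss (posterior-mean) estimates and
  shortest-window HPD credible intervals;
- **intervals** — observed-information (Wald) confidence intervals;
- **simulate** — a Monte-Carlo harness tabulating bias, MSE and
  interval lengths over grids of (θ, n, T);
- **model_select** — AIC/CAIC/BIC/HQIC, censored-data fits of
  exponential and two/three-parameter Fréchet competitors, and a
  modified Kolmogorov–Smirnov test for Type-I censored data with a
  parametric-bootstrap p-value.

## Worked example

Simulate a censored trial of the kind this toolkit targets — 40 units,
trial stopped at T = 205, generated from NEXF(0.5, 0.5, 0.5) — then fit
and compare candidate models:

```sh
nexf make-fixture --alpha 0.5 --beta 0.5 --lam 0.5 --n 40 \
     --censor-time 205 --seed 11 --out remission.csv
# wrote 39 observed times of n=40 to remission.csv

nexf fit --input remission.csv --n-total 40 --censor-time 205 \
     --method mle --out fit_out
```

which prints (abridged)

```
"estimates": { "alpha": 0.385, "beta": 0.401, "lam": 0.578 },
"ci_low":    { "lam": 0.289 },  "ci_high": { "lam": 0.867 }
```

— the maximum-likelihood estimate with 95% observed-information
intervals; the generating values (0.5, 0.5, 0.5) are inside every
interval. Model comparison with a 200-replicate bootstrap KS p-value:

```sh
nexf compare --input remission.csv --n-total 40 --censor-time 205 \
     --boot 200 --seed 3 --out cmp_out
```

```
             k      loglik         aic     ...        ks   p_value
NEXF         3   -61.411340  128.822680   ...  0.081478  0.572139
Exponential  1  -128.106639  258.213279   ...  0.629247  0.004975
Frechet2     2   -61.514582  127.029163   ...  0.085918  0.646766
Frechet3     3   -60.589755  127.179510   ...  0.068329  0.880597
best (min AIC): Frechet2
```

The exponential is decisively rejected (KS p ≈ 0.005); the Fréchet-type
models all fit, and at n = 40 the two-parameter Fréchet wins on parsimony
— with β as small as 0.5, forty censored observations rarely contain
enough signal to justify the third parameter, which is itself an honest
reading of this sample size.

A Monte-Carlo study is one YAML file away:

```sh
nexf simulate --config grid.yaml --out sim_out    # bias/MSE/CI-length table
```

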