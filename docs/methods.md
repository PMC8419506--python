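# Methods

## Model

The NEX-Fréchet distribution arises by pushing the Fréchet CDF
`F(x) = exp(−(α/x)^λ)` through the NEX transform

    G(x) = 1 − (1 − F(x)) e^{−β F(x)},   x, α, β, λ > 0,

with density `g = f (1 + β(1−F)) e^{−βF}`. Some presentations of the
family write the exponential tilt with a positive sign, `e^{+βF}`; that
version fails to be a distribution for β > 1 (its "density" goes
negative where `F < (β−1)/β`), and only the `−βF` form is consistent
with the family's series expansion, its Lambert-W quantile and its
likelihood. This package uses the `−βF` form everywhere.

Parameters, with units and roles:

- `alpha > 0` — Fréchet scale, same units as the data. Sets location of
  the distribution body.
- `lam > 0` — Fréchet tail index, dimensionless. `E[X^r]` exists iff
  `r < lam`; the package signals non-existent moments with
  `MomentDoesNotExistError` rather than returning inf or NaN.
- `beta ≥ 0` — NEX shape, dimensionless. Bends the hazard away from the
  Fréchet baseline; `beta = 0` is admitted as the limiting reference.

Quantiles are closed form: solving `G(x) = p` gives
`u = F(x) = 1 − W(β(1−p)e^β)/β` with `W` the principal Lambert branch,
then `x = α(−log u)^{−1/λ}`. `W(z)` is evaluated as
`wrightomega(log z)`, which neither overflows for large β nor
approaches a branch point (the argument is always positive), so random
generation by inverse transform is exact and vectorized.

The moment generating function is not provided: with a regularly
varying right tail, `E[e^{tX}] = ∞` for every `t > 0`, so the formal
series one could write for it diverges and no finite object exists to
compute.

## Series representation and moment functionals

Expanding `e^{−βF}` gives the linear representation

    g(x) = Σ_{m∈{0,1}} Σ_{k≥0} φ_{m,k} h_{m+k}(x),
    φ_{m,k} = (−1)^{m+k+1} β^k / k!,

where `h_j` is the Fréchet density with scale `α j^{1/λ}` (the j = 0
term carries no mass on x > 0). The sign `(−1)^{m+k+1}` is the one
under which the expansion reproduces the exact density; the tests
verify this to 1e−8 at truncation K = 40 for β ≤ 5. Raw moments,
incomplete moments (via **upper** incomplete gamma functions — the
t → ∞ limit fixes the flavor), mean residual life, mean inactivity
time, and the Lorenz/Bonferroni/Zenga curves are all evaluated
termwise from this expansion. The truncated tail is certified below
1e−8 before use; for large β (roughly β > K/2) the series is abandoned
for adaptive quadrature on the probability scale,
`E[X^s 1{X≤t}] = ∫₀^{G(t)} Q(p)^s dp`, which is robust under heavy
tails. Order statistics use the standard beta/binomial forms in
log-space rather than the equivalent but numerically fragile
hypergeometric closed form.

## Numerical conventions

- All densities and survival quantities are computed in log space;
  extreme arguments give exact 0/1/∞ limits, never NaN.
- `log(1 − e^{−t})` uses the two-regime `log1mexp` split (`expm1` below
  t = log 2, `log1p∘exp` above); this matters in the far lower tail
  where the first MPS spacing can be of order e^−1000.
- Finite-difference Hessians use relative steps `1e−4·max(1,|θ|)`
  (near the eps^¼ optimum for second differences) with one Richardson
  refinement where accuracy beats speed.
- Series truncation defaults to K = 40 with a 1e−12 tail-term stop.

## Estimation under Type-I censoring

The data model is `TypeICensoredSample(times, n_total, T)`; complete
samples are the case `T = ∞`. The censored log-likelihood is
`Σ log g(xᵢ) + (n−m) log S(T)`; the log-product-of-spacings objective
is `log G(x₁) + Σ log[G(xᵢ)−G(xᵢ₋₁)] + log S(x_m) + (n−m) log S(T)`,
which for complete data reduces to the usual (n+1)-spacing form (the
exponentiated spacings then sum to one). Both terms `log S(x_m)` and
`(n−m) log S(T)` are retained simultaneously for censored data, as the
objective is conventionally written for this sampling scheme. Tied
observations are jittered by a relative 1e−12 with a warning.

Three fitting protocols are exposed, because they answer different
questions:

1. **`fit_mle`/`fit_mps` (default, global):** simplex search on log
   parameters, first start from a Gumbel-moment fit of the Fréchet part
   (`sd(log X) = π/(λ√6)`) with β = 1, up to four deterministic
   perturbed restarts. This is the right tool for real data, where the
   answer should be the global optimum.
2. **`local=True`:** a single BFGS ascent from a caller-supplied start.
3. **`fit_newton`:** classical undamped Newton–Raphson on the score
   equations (finite-difference gradient and Hessian on log
   parameters, batched evaluation). It converges quadratically to the
   stationary point whose basin contains the start — and is declared
   converged only at a negative-definite Hessian — or diverges, which
   is reported, not hidden.

### Why the harness defaults to Newton–Raphson from the truth

At small `λ` and moderate n the model is **weakly identified along a
ridge**: inflating β and α while deflating λ produces nearly the same
fit (for small F, `G ≈ 1 − e^{−(1+β)F}`, so β trades off against the
effective scale). Finite samples then sometimes place the *global*
optimum far from the generating values (e.g. α̂ ≈ 35, β̂ ≈ 8, λ̂ ≈ 0.24
for data generated at (0.5, 0.5, 0.5), n = 200), and the sampling
distribution of the globally maximized estimator is wide and left
skewed in λ. Monte-Carlo studies of censored-data estimators in this
literature conventionally solve the score equations by Newton-type
iteration started at the generating values, which reports the local
solution near the truth when one exists and diverges otherwise.
`run_cell` therefore defaults to `solver="newton"` with the truth as
the start, **drops divergent replications and reports the drop count**
(cells losing more than 5% are flagged — at the ridge-prone settings
above the drop rate is large, roughly 40% for the likelihood and 75%
for the spacings objective, and the flag fires; the reported cell
statistics are explicitly conditional on convergence). `solver="local"`
and `solver="global"` rerun the same cells under the other protocols
for sensitivity analysis.

### Interval summaries in the harness

Two 95% interval-length summaries are reported per cell:

- `mean_ci_length` — the mean of per-replication observed-information
  Wald lengths (`2·1.959964·√V̂_λλ`, V̂ the inverse negative Hessian at
  the estimate). On ridged surfaces the per-sample Hessian is
  systematically flatter than the sampling spread, so this summary runs
  long.
- `mc_ci_length` — `2·1.959964 × (Monte-Carlo sd of the kept
  estimates)`, the normal-approximation length built from the actual
  sampling distribution. This is the construction under which a cell's
  bias/MSE/length triplet satisfies `MSE = bias² + (length/3.92)²`
  identically, and it is the one used for table work.

For a single real dataset only the observed-information construction is
available; `asymptotic_ci` provides it at the MLE or (same
construction, its own Hessian) at the MPS estimate, suppressing any
parameter whose variance estimate is non-positive.

## Bayesian estimation

Independent Gamma(bᵢ, dᵢ) priors on (α, β, λ); two ready-made choices:
`PriorSpec.diffuse()` (all Gamma(0.1, 0.1)) and
`PriorSpec.centered_at(θ₀, shape=2)` (prior mean θ₀, mildly
informative), the latter typically centered at a pilot MLE. Sampling is
Gaussian random-walk Metropolis–Hastings on log parameters with the
log-scale Jacobian in the target; proposal scales are adapted every 100
burn-in iterations toward a 20–40% acceptance window and then frozen,
so the retained chain is a valid fixed-kernel chain. Defaults
N = 12,000 / burn-in 2,000; chains are exactly reproducible under a
seed. Point estimates under squared-error loss are posterior means;
interval estimates are shortest-window HPD intervals from the sorted
draws (scan of all windows of ⌈(1−γ)N⌉ consecutive order statistics),
which are never longer than the equal-tailed interval by construction.
In the harness, Bayesian cells default to fewer replications than the
frequentist ones (hundreds rather than thousands) since each carries a
full chain.

## Model selection for censored data

Candidates: NEXF, exponential (`1 − e^{−rate·x}`; censored MLE in
closed form, `rate = m/(Σxᵢ + (n−m)T)`), two-parameter Fréchet, and
three-parameter Fréchet with location (kept strictly below the
smallest observation via the parametrization `μ = x_min − e^z`). All
are fitted under the same censored-likelihood skeleton. Criteria:
`AIC = 2k − 2ℓ`, `CAIC = 2nk/(n−k−1) − 2ℓ`, `BIC = k log n − 2ℓ`,
`HQIC = 2k log log n − 2ℓ`, with `n` the number of units on test (not
just observed failures). The headline winner is minimum AIC; all
criteria are reported.

Goodness of fit uses a modified KS statistic for Type-I censored data:
`D = maxᵢ max(i/n − Ĝ(x₍ᵢ₎), Ĝ(x₍ᵢ₎) − (i−1)/n)` over the observed
failures, with the empirical CDF on the n-unit scale so the censored
mass past T is handled correctly. Its null distribution is estimated by
parametric bootstrap: simulate n units from the fitted model, censor at
the same T, refit the same family, recompute D; the p-value is
`(1 + #{D_b ≥ D_obs})/(B + 1)`. Calibration (rejection rate ≈ nominal
level on self-simulated data) and power against gross misspecification
are exercised in the test suite with the closed-form exponential
candidate, keeping half a million bootstrap refits affordable.

## Synthetic data

`generate_censored_sample` draws i.i.d. NEXF variates by inverse
transform and truncates the record at T — exactly the Type-I censored
design it emulates (a trial of n units stopped at a fixed calendar
time). It does not emulate covariates, staggered entry, competing
risks, measurement rounding, or tied recording times, so passing tests
demonstrate correctness of the inferential machinery under the model,
not robustness to those real-data features. The packaged demonstration
fixture mirrors a small clinical remission-time study in shape — n = 40
units with a late censoring time T = 205 in day units — but is
synthetic; its generating parameters travel alongside it in a sidecar
file.

## Problem sizes

The test suite runs its Monte-Carlo cells at 1,500 replications and the
acceptance script at 10,000 (one to a few minutes per cell on one CPU);
`--reps` rescales. At 1,500 replications the Monte-Carlo standard error
of an MSE estimate is about 5% of its value, at 10,000 about 2%.

## Known limitations

- The (α, β) ridge at small λ is a property of the family, not of the
  code: with n in the low hundreds, global and truth-local optima can
  disagree materially, so every reported simulation cell must state its
  protocol. The package always reports which solver produced a number
  and how many replications were dropped.
- MPS estimates under the Newton protocol drop a large fraction of
  replications at ridge-prone settings; their conditional cell
  statistics are not comparable across protocols.
- The per-replication Wald lengths and the Monte-Carlo-sd lengths
  disagree precisely where identification is weak; both are reported
  so the disagreement is visible rather than averaged away.
- HPD intervals assume a unimodal marginal posterior; for strongly
  ridged posteriors the shortest window can clip a shoulder.
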