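# Methods

## Model and procedure

The package studies Bayesian leave-one-out cross-validation (LOO) as a
model-comparison criterion in the one case where everything is available in
closed form: a point null versus a conjugate alternative, evaluated on data
that agree exactly with the null.

For a model with parameter $\theta$, the leave-one-out predictive density of
observation $i$ is $p(y_i \mid y_{-i}) = \int p(y_i \mid \theta)\,
p(\theta \mid y_{-i})\, d\theta$, and
$\mathrm{elpd}_{\mathrm{loo}} = \sum_i \log p(y_i \mid y_{-i})$.
A point null has no free parameter, so its elpd is the summed log
likelihood at the fixed parameter value. Two models are compared by
$\Delta\mathrm{elpd}$ (null minus alternative), the pseudo-Bayes factor
$\mathrm{PSBF}_{01} = e^{\Delta\mathrm{elpd}}$, and softmax weights.

Three comparisons are implemented:

1. **Induction** — H0: $\theta = 1$ vs H1: $\theta \sim \mathrm{Beta}(a,b)$,
   on $n$ observed successes. The held-out posterior is
   $\mathrm{Beta}(a+n-1,\, b)$ and the predictive success probability is its
   mean, the $(a,b)$-general rule of succession, giving
   $\Delta\mathrm{elpd} = -n \log\frac{a+n-1}{a+n-1+b} \to b$.
   The asymptotic support depends on the prior — the shape $b$ controls how
   much mass the alternative keeps away from $\theta = 1$.
2. **Chance** — H0: $\theta = 1/2$ vs the same Beta alternative, on even $n$
   with exactly $n/2$ successes:
   $\Delta\mathrm{elpd} = \frac n2 \log\frac{a+b+n-1}{2a+n-2}
   + \frac n2 \log\frac{a+b+n-1}{2b+n-2} \to 1$, independent of $(a,b)$.
3. **Normal mean** — H0: $\mu = 0$ vs H1: $\mu \sim \mathcal N(0, \sigma_0^2)$
   with known unit observation variance, on data standardized so
   $\bar y = 0$ and $s^2 = 1$ exactly. With $\tau = 1/\sigma_0^2$,
   $\Delta\mathrm{elpd} = \frac n2 \log\frac{n+\tau}{n-1+\tau}
   + \frac{n-1}{2(n-1+\tau)} \to 1$, independent of $\sigma_0^2$.

The bounded limits mean LOO is inconsistent for a true point null: the null
weight converges to $e^b/(1+e^b)$ or $e/(1+e) \approx 0.731$ rather than 1.
For contrast, `bayes_factor` computes the marginal-likelihood Bayes factor
for the same comparisons (Beta-function identity for Bernoulli; the
known-variance normal closed form $\mathrm{BF}_{01} = \sqrt{1+n\sigma_0^2}\,
e^{-\sigma_0^2 (\sum y_i)^2 / (2(1+n\sigma_0^2))}$), which diverges on the
same data. It is a deliberately separate feature, not part of the LOO core.

A maximum-likelihood variant of the induction comparison is included as
`mle_loo_induction`: every training fold estimates $\hat\theta = 1$, both
models predict the held-out success with probability one, and
$\Delta\mathrm{elpd} = 0$ identically — plug-in LOO finds all-successes
data completely uninformative.

## Parameters

| parameter | meaning | domain | defaults used |
|---|---|---|---|
| $a, b$ | Beta prior shapes of the Bernoulli alternative | $> 0$ | figure grid $(1,5), (5,5), (2,2), (1,1), (0.5,0.5)$ |
| $\sigma_0^2$ | prior variance of the normal-mean alternative | $> 0$ | figure grid $\sigma_0 \in \{3, 1.5, 1, 0.5\}$; $\sigma_0 = 2.035$ for the nonmonotone case |
| $\theta_0$, $\mu_0$ | point-null values | $[0,1]$ / $\mathbb R$ | $1$, $1/2$, $0$ in the three examples |
| $n$ | sample size | integer for data; real $\ge 2$ for the smooth closed forms | grids below |

The prior grids are the ones the weight-versus-$n$ figures are defined on;
the CLI and library accept arbitrary valid values.

## Synthetic data

The generators produce the idealized regimes the closed forms assume:
all-successes, exactly-half-successes (alternating 1,0 pairs — the order is
provably irrelevant because the Bernoulli leave-one-out predictive depends
only on the total success count and the held-out value, and a test asserts
this), and normal samples affinely transformed so the sample mean is
exactly 0 and the sample variance (n−1 denominator) exactly 1. The affine
standardization matches the convention of the normal example; it makes the
data *deterministically* law-consistent, which is the study condition, not
an approximation. `sample_from_model` adds genuinely stochastic Bernoulli
or normal draws for property tests.

What the generators deliberately do not emulate: sampling variability
around the null in the idealized regimes (real data would have
$k/n \approx 1/2$, not exactly $1/2$), covariates, unknown observation
variance, or model misspecification. Passing tests therefore demonstrate
the analytic behaviour of LOO under exact law-consistency, not its
behaviour on noisy real data, where $\Delta\mathrm{elpd}$ fluctuates around
these curves.

## Numerical choices

- **Large-$n$ stability.** Every ratio of the form $(n+c_1)/(n+c_2)$ inside
  a log is evaluated as $\mathrm{log1p}((c_1-c_2)/(n+c_2))$; multiplied by
  $n$, the naive form loses all precision around $n \approx 10^8$ while the
  log1p form is accurate beyond $10^{12}$. An optional `dps` argument
  evaluates the same expressions in mpmath arbitrary precision (50 digits
  are used for the $n = 10^{10}$ limit checks).
- **Quadrature oracle.** The oracle never reuses the conjugate closed
  forms: it normalizes prior × training likelihood numerically and
  integrates the predictive integral with adaptive quadrature
  (`scipy.integrate.quad`). Beta integrands are mapped through
  $\theta = \sin^2 u$, which removes the endpoint singularities of shapes
  below 1 (the Jeffreys prior $\mathrm{Beta}(0.5, 0.5)$ is a headline case
  and must pass); normal integrands run over ±10 posterior standard
  deviations, beyond which the omitted mass is far below the $10^{-8}$
  agreement tolerance. Oracle grids use $n \le 16$ (Bernoulli, all $k$) and
  $n \le 50$ (normal), which keeps the full oracle-equivalence sweep at a
  few seconds while covering every qualitative regime.
- **Falsified nulls.** $\theta_0 = 1$ with an observed failure has zero
  predictive probability; elpd is reported as $-\infty$ and propagates
  through comparisons as PSBF 0 and weights (0, 1). This is a legitimate
  model falsification, not an error; only a comparison of *two* falsified
  models raises.
- **Overflow-safe weights.** elpd scales linearly in $n$ and
  $e^{\mathrm{elpd}}$ overflows by $n \approx 1500$; weights use
  max-subtracted exponentiation throughout.
- **Shape classification.** Trajectory monotonicity uses a tolerance of
  $10^{-12}$ on successive weight differences to separate true
  nonmonotonicity from rounding jitter.
- **Extremum location.** The closed forms are smooth in real-valued $n$, so
  interior extrema of $\Delta\mathrm{elpd}(n)$ are located by scanning a
  geometric grid for a sign change of the central-difference derivative
  (step $h = \max(10^{-4} n, 10^{-3})$) and refining by Brent's method.
  Existence, not exact location, is the claim being verified — e.g. the
  $\sigma_0 = 2.035$ prior has an interior maximum near $n \approx 6$.

## Design choices

- Sample-size grids for the trajectory curves: a dense integer range
  (1–200 for induction, even 2–400 for chance, 2–200 for normal) covering
  the visual range of the published figures, plus a geometric tail to
  $10^6$ (rounded to even for chance) probing the asymptote. The published
  figures do not state their grids; these are this package's choice.
- 0-based indexing for per-point predictives in the API;
  datasets are immutable value types with derived counts recomputed rather
  than stored.
- Asymptotic limits are implemented as the stated closed-form values and
  verified numerically (convergence of $\Delta\mathrm{elpd}(n)$ at
  $n = 10^8$–$10^{12}$), not re-derived symbolically.
- JSON/CSV artifacts carry 12 significant digits and sorted keys so
  identical configurations reproduce byte-identically.

## Known limitations

- Only the two conjugate families are supported; there is no MCMC or
  importance-sampling LOO path, because every posterior here is available
  exactly.
- The chance closed form accepts real-valued $n$ for smooth analysis but
  rejects odd integers; the continuous interpolation through odd $n$ has no
  data interpretation.
- The normal family fixes the observation variance at 1 and the prior mean
  at 0; unknown-variance and shifted-prior variants are out of scope.
- `bayes_factor` covers exactly the implemented comparisons (it requires
  $\mu_0 = 0$ in the normal family); it exists for contrast, not as a
  general Bayes-factor engine.
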