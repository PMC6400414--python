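# loobound

Exact Bayesian leave-one-out cross-validation (LOO) for point-null model
comparisons in conjugate families, built to quantify a counterintuitive
property of LOO as a model-selection tool: **even when a data set of
unlimited size agrees perfectly with a simple point-null model, LOO's
support for that model stays bounded — and surprisingly modest**.

The package is aimed at statisticians and computational researchers in the
behavioural and life sciences who use out-of-sample predictive criteria
(elpd, pseudo-Bayes factors, LOO weights) to compare models and want a
concrete, fully analytic testbed for how those criteria behave when a
general law is exactly true.

## The setting

For observations $y_1,\dots,y_n$, LOO estimates the expected log pointwise
predictive density

$$\mathrm{elpd}_{\mathrm{loo}} = \sum_{i=1}^n \log p(y_i \mid y_{-i}),
\qquad
p(y_i \mid y_{-i}) = \int p(y_i \mid \theta)\, p(\theta \mid y_{-i})\, d\theta .$$

Two models are compared through the pseudo-Bayes factor
$\mathrm{PSBF}_{01} = \exp\{\Delta \mathrm{elpd}_{\mathrm{loo}}\}$ and the
softmax model weights $w_m \propto \exp\{\mathrm{elpd}^{(m)}\}$.

Three conjugate comparisons are implemented, each pairing a point null with
an alternative that relaxes it, on data *exactly* consistent with the null:

| example       | null              | alternative                        | data                          | $\lim_{n\to\infty}\Delta\mathrm{elpd}$ |
|---------------|-------------------|------------------------------------|-------------------------------|-----|
| `induction`   | $\theta = 1$      | $\theta \sim \mathrm{Beta}(a,b)$   | all $n$ successes             | $b$ |
| `chance`      | $\theta = 1/2$    | $\theta \sim \mathrm{Beta}(a,b)$   | $n$ even, exactly $n/2$ successes | $1$ |
| `normal_mean` | $\mu = 0$         | $\mu \sim \mathcal N(0,\sigma_0^2)$, $\sigma^2=1$ known | $\bar y = 0$, $s^2 = 1$ exactly | $1$ |

The finite limits are the point: a true general law never earns more than
$\mathrm{PSBF}_{01} \to e^b$ (induction) or $e \approx 2.718$ — a LOO
weight of only $e/(1+e) \approx 0.731$ — while the ordinary
marginal-likelihood Bayes factor on the same data grows without bound.
Depending on the prior, the weight can even *decrease*, or rise and then
fall, as perfectly law-consistent observations accumulate.

The package provides the closed-form elpd expressions and their limits
(stable to $n = 10^{12}$ in double precision, arbitrary precision on
request), a generic analytic LOO engine for both families, an independent
quadrature oracle that integrates the predictive density directly,
weight-versus-$n$ trajectory analysis with shape classification and
extremum location, and generators for the idealized datasets.

## Worked example

Generate two success/failure pairs and compare the chance law
$\theta = 1/2$ against a uniform-prior alternative:

```bash
$ loobound generate --regime half-successes --n 4 --out pairs.txt
wrote 4 values to pairs.txt
$ loobound compare pairs.txt --family bernoulli --null-value 0.5 --prior 1,1 --bf
{
  "bf01": 1.875,
  "delta_elpd": 0.892574205257,
  "n": 4,
  "psbf01": 2.44140625,
  "w0": 0.709421112372,
  "w1": 0.290578887628
}
```

The null out-predicts the alternative by $\Delta\mathrm{elpd} =
2\log(5/4) + 2\log(5/4) \approx 0.893$, a pseudo-Bayes factor of about 2.44
and a null weight of 0.709 — already close to the ceiling this comparison
can ever reach:

```bash
$ loobound limits --example chance --prior 1,1
{
  "delta_elpd_limit": 1.0,
  "example": "chance",
  "psbf_limit": 2.71828182846,
  "w0_limit": 0.73105857863
}
```

No matter how many perfectly balanced pairs are observed, the LOO weight of
the true chance law never exceeds $e/(1+e) \approx 0.731$. The
`bf01` field shows the contrast: the marginal-likelihood Bayes factor keeps
growing with $n$ on the same data.

The weight-versus-$n$ curves behind the three standard figures, including
the prior choices that approach the bound from above or nonmonotonically:

```bash
$ loobound figure --id 2 --out fig2.csv --plot fig2.png
wrote 1395 rows (5 curves) to fig2.csv
$ loobound trajectory --example normal_mean --prior 2.035 --out traj.csv
{"asymptote": 0.73105857863, "points": 278, "shape": "nonmonotone"}
```

From Python the same computation is three lines:

```python
from loobound import BetaPrior, delta_elpd_chance, limits

delta_elpd_chance(BetaPrior(1, 1), n=4)      # 0.8925742052568391
limits("chance", BetaPrior(1, 1)).w0_limit   # 0.7310585786300049
```

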