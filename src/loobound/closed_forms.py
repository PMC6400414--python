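"""Closed-form elpd_loo expressions and asymptotic limits for the three examples.

Each example pairs a point null with a conjugate alternative on data that
agree exactly with the null:

* ``induction``  — H0: θ = 1  vs  H1: θ ~ Beta(a, b), all n observations
  successes.  Δelpd_loo = -n log((a+n-1)/(a+n-1+b)), with limit b: the
  asymptotic support depends on the prior.
* ``chance``     — H0: θ = 1/2 vs H1: θ ~ Beta(a, b), even n with exactly
  n/2 successes.  Δelpd_loo = (n/2)[log((a+b+n-1)/(2a+n-2)) +
  log((a+b+n-1)/(2b+n-2))], with prior-independent limit 1.
* ``normal_mean``— H0: μ = 0  vs  H1: μ ~ N(0, σ₀²), unit known variance,
  sample mean exactly 0 and sample variance exactly 1.
  Δelpd_loo = (n/2) log((n+1/σ₀²)/(n-1+1/σ₀²)) + (n-1)/(2(n-1+1/σ₀²)),
  again with limit 1.

Δelpd is H0 minus H1 throughout, so a positive value favours the null.  The
bounded limits are the central phenomenon: the pseudo-Bayes factor for a
*true* point null converges to exp(Δ∞) — e.g. e ≈ 2.718, a model weight of
only ≈ 0.731 — instead of diverging.

Ratios of the form (n + c1)/(n + c2) are evaluated via log1p((c1-c2)/(n+c2))
so the expressions remain accurate up to n ≈ 1e12 in double precision; an
optional ``dps`` argument switches to mpmath arbitrary precision.  Sample
sizes may be real-valued (the expressions are smooth in n), which the
trajectory analysis uses for continuous-n extremum location; integer parity
is still enforced for the chance example.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import mpmath as mp

from .loo import BetaPrior, NormalMeanPrior

__all__ = [
    "ExampleSpec",
    "LimitResult",
    "EXAMPLE_IDS",
    "elpd_h0_induction",
    "elpd_h0_chance",
    "elpd_h0_normal",
    "elpd_h1_induction",
    "elpd_h1_chance",
    "elpd_h1_normal",
    "delta_elpd_induction",
    "delta_elpd_chance",
    "delta_elpd_normal",
    "delta_elpd",
    "limits",
    "mle_loo_induction",
]

EXAMPLE_IDS = ("induction", "chance", "normal_mean")

Prior = Union[BetaPrior, NormalMeanPrior]


@dataclass(frozen=True)
class ExampleSpec:
    """One of the three model comparisons at a given sample size."""

    example_id: str
    prior: Prior
    n: float

    def __post_init__(self) -> None:
        _check_example(self.example_id, self.prior)
        _check_n(self.example_id, self.n)


@dataclass(frozen=True)
class LimitResult:
    """Asymptotic Δelpd, pseudo-Bayes factor and null-model weight."""

    delta_elpd_limit: float
    psbf_limit: float
    w0_limit: float


def _check_example(example_id: str, prior: Prior) -> None:
    if example_id not in EXAMPLE_IDS:
        raise ValueError(f"unknown example {example_id!r}; expected one of {EXAMPLE_IDS}")
    if example_id in ("induction", "chance") and not isinstance(prior, BetaPrior):
        raise TypeError(f"{example_id} requires a BetaPrior")
    if example_id == "normal_mean" and not isinstance(prior, NormalMeanPrior):
        raise TypeError("normal_mean requires a NormalMeanPrior")


def _check_n(example_id: str, n: float, *, require_int: bool = False) -> float:
    n = float(n)
    if not math.isfinite(n):
        raise ValueError(f"sample size must be finite, got {n}")
    minimum = 1.0 if example_id == "induction" else 2.0
    if n < minimum:
        raise ValueError(f"{example_id} requires n >= {int(minimum)}, got {n}")
    if example_id == "chance" and n.is_integer() and int(n) % 2 != 0:
        raise ValueError(f"chance requires an even sample size, got n={int(n)}")
    if require_int and not n.is_integer():
        raise ValueError(f"integer sample size required, got {n}")
    return n


def _log1p(x, dps):
    if dps is None:
        return math.log1p(x)
    return mp.log1p(x)


def _as_float(x) -> float:
    return float(x)


# -- H0 closed forms ---------------------------------------------------------


def elpd_h0_induction(n: float) -> float:
    """elpd_loo of H0: θ=1 on all-successes data: every prediction is certain."""
    _check_n("induction", n)
    return 0.0


def elpd_h0_chance(n: float) -> float:
    """elpd_loo of H0: θ=1/2 on any Bernoulli data of size n: -n log 2."""
    _check_n("chance", n)
    return -float(n) * math.log(2.0)


def elpd_h0_normal(n: float) -> float:
    """elpd_loo of H0: μ=0 on standardized data: -(n/2) log 2π - (n-1)/2."""
    _check_n("normal_mean", n)
    n = float(n)
    return -(n / 2.0) * math.log(2.0 * math.pi) - (n - 1.0) / 2.0


# -- Δelpd closed forms ------------------------------------------------------


def delta_elpd_induction(prior: BetaPrior, n: float, dps: int | None = None) -> float:
    """Δelpd_loo (H0 - H1) for the induction example; limit is b."""
    n = _check_n("induction", n)
    a, b = prior.a, prior.b
    if dps is None:
        return n * math.log1p(b / (a + n - 1.0))
    with mp.workdps(dps):
        nn = mp.mpf(n)
        return _as_float(nn * mp.log1p(mp.mpf(b) / (mp.mpf(a) + nn - 1)))


def delta_elpd_chance(prior: BetaPrior, n: float, dps: int | None = None) -> float:
    """Δelpd_loo (H0 - H1) for the chance example; prior-independent limit 1."""
    n = _check_n("chance", n)
    a, b = prior.a, prior.b
    # (a+b+n-1)/(2a+n-2) = 1 + (b+1-a)/(2a+n-2), and symmetrically in a<->b
    if dps is None:
        return (n / 2.0) * (
            math.log1p((b + 1.0 - a) / (2.0 * a + n - 2.0))
            + math.log1p((a + 1.0 - b) / (2.0 * b + n - 2.0))
        )
    with mp.workdps(dps):
        nn, aa, bb = mp.mpf(n), mp.mpf(a), mp.mpf(b)
        return _as_float(
            (nn / 2)
            * (
                mp.log1p((bb + 1 - aa) / (2 * aa + nn - 2))
                + mp.log1p((aa + 1 - bb) / (2 * bb + nn - 2))
            )
        )


def delta_elpd_normal(
    prior: NormalMeanPrior, n: float, dps: int | None = None
) -> float:
    """Δelpd_loo (H0 - H1) for the normal-mean example; prior-independent limit 1."""
    n = _check_n("normal_mean", n)
    tau = 1.0 / prior.sigma0_sq
    if dps is None:
        d = n - 1.0 + tau
        return (n / 2.0) * math.log1p(1.0 / d) + (n - 1.0) / (2.0 * d)
    with mp.workdps(dps):
        nn = mp.mpf(n)
        tt = 1 / mp.mpf(prior.sigma0_sq)
        d = nn - 1 + tt
        return _as_float((nn / 2) * mp.log1p(1 / d) + (nn - 1) / (2 * d))


_DELTA = {
    "induction": delta_elpd_induction,
    "chance": delta_elpd_chance,
    "normal_mean": delta_elpd_normal,
}


def delta_elpd(
    example_id: str, prior: Prior, n: float, dps: int | None = None
) -> float:
    """Dispatch Δelpd_loo (H0 - H1) by example id."""
    _check_example(example_id, prior)
    return _DELTA[example_id](prior, n, dps)


# -- H1 closed forms ---------------------------------------------------------


def elpd_h1_induction(prior: BetaPrior, n: float) -> float:
    """elpd_loo of H1: θ~Beta(a,b) on all-successes data: n log((a+n-1)/(a+n-1+b))."""
    n = _check_n("induction", n)
    a, b = prior.a, prior.b
    return -n * math.log1p(b / (a + n - 1.0))


def elpd_h1_chance(prior: BetaPrior, n: float) -> float:
    """elpd_loo of H1 on k=n/2 data: (n/2)[log term for successes + for failures]."""
    n = _check_n("chance", n)
    a, b = prior.a, prior.b
    denom = a + b + n - 1.0
    return (n / 2.0) * (
        math.log((a + n / 2.0 - 1.0) / denom) + math.log((b + n / 2.0 - 1.0) / denom)
    )


def elpd_h1_normal(prior: NormalMeanPrior, n: float) -> float:
    """elpd_loo of H1: μ~N(0,σ₀²) on standardized data (three-term closed form)."""
    n = _check_n("normal_mean", n)
    tau = 1.0 / prior.sigma0_sq
    d = n - 1.0 + tau
    return (
        -(n / 2.0) * math.log(2.0 * math.pi)
        - (n / 2.0) * math.log1p(1.0 / d)
        - (n - 1.0) * (n + tau) / (2.0 * d)
    )


# -- Limits and the MLE variant ---------------------------------------------


def limits(example_id: str, prior: Prior) -> LimitResult:
    """Asymptotic (n → ∞) Δelpd, PSBF01 and w0 for an example/prior pair.

    The induction limit is the prior shape b — asymptotically prior
    dependent.  The chance and normal limits are 1 regardless of the prior,
    giving PSBF01 → e and w0 → e/(1+e) ≈ 0.731.
    """
    _check_example(example_id, prior)
    if example_id == "induction":
        d = float(prior.b)  # type: ignore[union-attr]
    else:
        d = 1.0
    psbf = math.exp(d)
    return LimitResult(delta_elpd_limit=d, psbf_limit=psbf, w0_limit=psbf / (1.0 + psbf))


def mle_loo_induction(n: float) -> float:
    """Δelpd of maximum-likelihood LOO on all-successes data: exactly 0.

    Every training fold of size n-1 contains only successes, so the MLE
    under the alternative is θ̂ = 1 — identical to the null's fixed value.
    Both models then make the same (perfect) test-set predictions and the
    data are completely uninformative, for every n.
    """
    n = _check_n("induction", n)
    if n < 2:
        raise ValueError("MLE LOO needs a nonempty training fold, so n >= 2")
    return 0.0
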