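"""Idealized and stochastic datasets for the three point-null comparisons.

The three study regimes are datasets that agree *exactly* with their
point-null model:

1. ``make_all_successes`` — n Bernoulli observations, all 1 (the induction
   regime, H0: theta = 1);
2. ``make_half_successes`` — n even Bernoulli observations with exactly n/2
   successes (the chance regime, H0: theta = 1/2);
3. ``make_standardized_normal`` — n normal observations affinely rescaled so
   the sample mean is exactly 0 and the sample variance (n-1 denominator) is
   exactly 1 (the z-test regime, H0: mu = 0).

``sample_from_model`` provides genuinely noisy draws from either likelihood
for property tests and oracle checks.  All randomness is driven by explicit
integer seeds; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "BernoulliDataset",
    "NormalDataset",
    "make_all_successes",
    "make_half_successes",
    "make_standardized_normal",
    "sample_from_model",
    "read_values",
    "write_values",
]


@dataclass(frozen=True)
class BernoulliDataset:
    """A sequence of binary outcomes with success count bookkeeping.

    Attributes
    ----------
    y : tuple of int
        Outcomes, each 0 or 1.
    """

    y: tuple[int, ...]

    def __post_init__(self) -> None:
        y = tuple(int(v) for v in self.y)
        if len(y) < 1:
            raise ValueError("Bernoulli dataset needs at least one observation")
        if any(v not in (0, 1) for v in y):
            raise ValueError("Bernoulli outcomes must be 0 or 1")
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        """Total number of successes."""
        return sum(self.y)

    def k_minus(self, i: int) -> int:
        """Success count with observation ``i`` (0-based) held out."""
        return self.k - self.y[i]


@dataclass(frozen=True)
class NormalDataset:
    """A sequence of real-valued observations (unit known variance model).

    ``ybar`` and ``s2`` are always recomputed from ``y``; the sample variance
    uses the n-1 denominator and requires n >= 2.
    """

    y: tuple[float, ...]

    def __post_init__(self) -> None:
        y = tuple(float(v) for v in self.y)
        if len(y) < 1:
            raise ValueError("Normal dataset needs at least one observation")
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def ybar(self) -> float:
        return float(np.mean(self.y))

    @property
    def s2(self) -> float:
        if self.n < 2:
            raise ValueError("sample variance undefined for n < 2")
        return float(np.var(self.y, ddof=1))

    def ybar_minus(self, i: int) -> float:
        """Mean of the observations with point ``i`` (0-based) held out."""
        if self.n < 2:
            raise ValueError("leave-one-out mean undefined for n < 2")
        return (self.n * self.ybar - self.y[i]) / (self.n - 1)


def make_all_successes(n: int) -> BernoulliDataset:
    """n Bernoulli observations, all successes (induction regime)."""
    n = _check_size(n, minimum=1)
    return BernoulliDataset(y=(1,) * n)


def make_half_successes(n: int) -> BernoulliDataset:
    """n even Bernoulli observations with exactly n/2 successes.

    The data are laid out as alternating success/failure pairs
    (1, 0, 1, 0, ...).  The ordering is irrelevant to every leave-one-out
    quantity computed downstream — the per-point predictive depends only on
    the total success count and the held-out value — but a fixed ordering
    keeps generation deterministic.
    """
    n = _check_size(n, minimum=2)
    if n % 2 != 0:
        raise ValueError(
            f"the chance regime requires an even sample size, got n={n}"
        )
    return BernoulliDataset(y=(1, 0) * (n // 2))


def make_standardized_normal(n: int, seed: int) -> NormalDataset:
    """n normal draws rescaled so ybar = 0 and s^2 = 1 exactly.

    Draws n standard-normal values with the given seed, subtracts the sample
    mean and divides by the sample standard deviation (n-1 denominator).
    Degenerate draws with zero spread are re-drawn.
    """
    n = _check_size(n, minimum=2)
    rng = np.random.default_rng(seed)
    for _ in range(100):
        raw = rng.standard_normal(n)
        sd = np.std(raw, ddof=1)
        if sd > 0:
            y = (raw - raw.mean()) / sd
            # one re-centering pass absorbs rounding in the first transform
            y = y - y.mean()
            return NormalDataset(y=tuple(float(v) for v in y))
    raise RuntimeError("could not draw a non-degenerate normal sample")


def sample_from_model(
    family: str, value: float, n: int, seed: int
) -> Union[BernoulliDataset, NormalDataset]:
    """i.i.d. draws from the stated likelihood (noisy variants).

    Parameters
    ----------
    family : {"bernoulli", "normal"}
    value : float
        Success probability theta in [0, 1], or normal mean mu (unit
        variance).
    """
    n = _check_size(n, minimum=1)
    rng = np.random.default_rng(seed)
    if family == "bernoulli":
        theta = float(value)
        if not 0.0 <= theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {theta}")
        return BernoulliDataset(y=tuple(int(v) for v in rng.binomial(1, theta, n)))
    if family == "normal":
        mu = float(value)
        if not np.isfinite(mu):
            raise ValueError(f"mu must be finite, got {mu}")
        return NormalDataset(y=tuple(float(v) for v in rng.normal(mu, 1.0, n)))
    raise ValueError(f"unknown family {family!r}")


def read_values(path: str | Path) -> list[float]:
    """Read a one-value-per-line text file; blank lines and ``#`` comments are skipped."""
    values: list[float] = []
    for line in Path(path).read_text().splitlines():
        stripped = line.split("#", 1)[0].strip()
        if stripped:
            values.append(float(stripped))
    return values


def write_values(path: str | Path, values: Iterable[float]) -> None:
    """Write values one per line; integers are written without a decimal point."""
    lines = []
    for v in values:
        f = float(v)
        lines.append(str(int(f)) if f.is_integer() else repr(f))
    Path(path).write_text("\n".join(lines) + "\n")


def _check_size(n: int, minimum: int) -> int:
    if not float(n).is_integer():
        raise ValueError(f"sample size must be an integer, got {n}")
    n = int(n)
    if n < minimum:
        raise ValueError(f"sample size must be >= {minimum}, got {n}")
    return n
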