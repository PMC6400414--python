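"""Closed-form elpd expressions: frozen values, identities, limits, stability."""

import math

import pytest

from loobound import (
    BetaPrior,
    NormalMeanPrior,
    PointNull,
    delta_elpd,
    delta_elpd_chance,
    delta_elpd_induction,
    delta_elpd_normal,
    elpd_h0_chance,
    elpd_h0_induction,
    elpd_h0_normal,
    elpd_h1_chance,
    elpd_h1_induction,
    elpd_h1_normal,
    limits,
    loo_analytic,
    make_all_successes,
    make_half_successes,
    make_standardized_normal,
    mle_loo_induction,
)

BETA_GRID = [BetaPrior(a, b) for a in (0.5, 1, 2, 5) for b in (0.5, 1, 2, 5)]
NORMAL_GRID = [NormalMeanPrior(v) for v in (0.25, 1.0, 2.25, 9.0)]


class TestFrozenValues:
    def test_induction_uniform_n2(self):
        got = delta_elpd_induction(BetaPrior(1, 1), 2)
        assert got == pytest.approx(2 * math.log(1.5), rel=1e-14)

    def test_chance_uniform_n2(self):
        got = delta_elpd_chance(BetaPrior(1, 1), 2)
        assert got == pytest.approx(2 * math.log(1.5), rel=1e-14)

    def test_normal_unit_prior_n2(self):
        got = delta_elpd_normal(NormalMeanPrior(1.0), 2)
        assert got == pytest.approx(math.log(1.5) + 0.25, rel=1e-14)

    def test_h1_closed_forms_n2(self):
        assert elpd_h1_induction(BetaPrior(1, 1), 2) == pytest.approx(2 * math.log(2 / 3))
        assert elpd_h1_chance(BetaPrior(1, 1), 2) == pytest.approx(2 * math.log(1 / 3))
        # sigma0^2=1, n=2: -(log 2π) - log(3/2) - 3/4
        got = elpd_h1_normal(NormalMeanPrior(1.0), 2)
        assert got == pytest.approx(-math.log(2 * math.pi) - math.log(1.5) - 0.75, rel=1e-13)

    def test_vague_normal_prior_n2(self):
        # 1/sigma0^2 -> 0: delta -> log 2 + 1/2
        got = delta_elpd_normal(NormalMeanPrior(1e14), 2)
        assert got == pytest.approx(math.log(2.0) + 0.5, rel=1e-6)


class TestIdentities:
    @pytest.mark.parametrize("prior", BETA_GRID)
    @pytest.mark.parametrize("n", [1, 2, 7, 40])
    def test_induction_delta_is_h0_minus_h1(self, prior, n):
        d = elpd_h0_induction(n) - elpd_h1_induction(prior, n)
        assert delta_elpd_induction(prior, n) == pytest.approx(d, abs=1e-12)

    @pytest.mark.parametrize("prior", BETA_GRID)
    @pytest.mark.parametrize("n", [2, 8, 40])
    def test_chance_delta_is_h0_minus_h1(self, prior, n):
        d = elpd_h0_chance(n) - elpd_h1_chance(prior, n)
        assert delta_elpd_chance(prior, n) == pytest.approx(d, abs=1e-12)

    @pytest.mark.parametrize("prior", NORMAL_GRID)
    @pytest.mark.parametrize("n", [2, 8, 40])
    def test_normal_delta_is_h0_minus_h1(self, prior, n):
        d = elpd_h0_normal(n) - elpd_h1_normal(prior, n)
        assert delta_elpd_normal(prior, n) == pytest.approx(d, abs=1e-12)

    def test_symmetric_chance_prior_has_equal_terms(self):
        # a = b makes the two log terms of the chance expression identical
        for n in (2, 10, 100):
            one_term = (n / 2) * math.log((2 + 2 + n - 1) / (2 * 2 + n - 2))
            assert delta_elpd_chance(BetaPrior(2, 2), n) == pytest.approx(2 * one_term)


class TestEngineConsistency:
    """The example-specific expressions must reproduce the generic LOO engine
    on the corresponding idealized datasets."""

    @pytest.mark.parametrize("prior", BETA_GRID)
    @pytest.mark.parametrize("n", [1, 3, 16])
    def test_induction(self, prior, n):
        ds = make_all_successes(n)
        engine = (
            loo_analytic(PointNull("bernoulli", 1.0), ds).elpd
            - loo_analytic(prior, ds).elpd
        )
        assert delta_elpd_induction(prior, n) == pytest.approx(engine, abs=1e-10)

    @pytest.mark.parametrize("prior", BETA_GRID)
    @pytest.mark.parametrize("n", [2, 6, 24])
    def test_chance(self, prior, n):
        ds = make_half_successes(n)
        engine = (
            loo_analytic(PointNull("bernoulli", 0.5), ds).elpd
            - loo_analytic(prior, ds).elpd
        )
        assert delta_elpd_chance(prior, n) == pytest.approx(engine, abs=1e-10)

    @pytest.mark.parametrize("prior", NORMAL_GRID)
    @pytest.mark.parametrize("n", [2, 6, 24])
    def test_normal(self, prior, n):
        ds = make_standardized_normal(n, seed=n + 1)
        engine = (
            loo_analytic(PointNull("normal", 0.0), ds).elpd
            - loo_analytic(prior, ds).elpd
        )
        assert delta_elpd_normal(prior, n) == pytest.approx(engine, abs=1e-10)


class TestLimits:
    def test_limit_values(self):
        lim = limits("induction", BetaPrior(1, 1))
        assert lim.delta_elpd_limit == 1.0
        assert lim.w0_limit == pytest.approx(math.e / (1 + math.e))
        lim5 = limits("induction", BetaPrior(1, 5))
        assert lim5.delta_elpd_limit == 5.0
        assert lim5.w0_limit == pytest.approx(math.exp(5) / (1 + math.exp(5)))
        for ex, prior in (("chance", BetaPrior(2, 5)), ("normal_mean", NormalMeanPrior(4.0))):
            lim = limits(ex, prior)
            assert lim.delta_elpd_limit == 1.0
            assert lim.psbf_limit == pytest.approx(math.e)

    def test_limit_invariants(self):
        lim = limits("induction", BetaPrior(2, 3))
        assert lim.psbf_limit == pytest.approx(math.exp(lim.delta_elpd_limit))
        assert lim.w0_limit == pytest.approx(lim.psbf_limit / (1 + lim.psbf_limit))

    @pytest.mark.parametrize(
        "ex,prior",
        [("induction", BetaPrior(0.5, 0.5)), ("induction", BetaPrior(1, 5)),
         ("chance", BetaPrior(0.5, 0.5)), ("chance", BetaPrior(1, 5)),
         ("normal_mean", NormalMeanPrior(0.25)), ("normal_mean", NormalMeanPrior(9.0))],
    )
    def test_eventual_monotone_convergence(self, ex, prior):
        lim = limits(ex, prior).delta_elpd_limit
        gaps = [abs(delta_elpd(ex, prior, n) - lim) for n in (1e4, 1e6, 1e8)]
        assert gaps[-1] < 1e-4
        assert gaps[0] > gaps[1] > gaps[2]

    def test_prior_independence_of_chance_and_normal_limits(self):
        for prior in BETA_GRID:
            assert abs(delta_elpd_chance(prior, 1e10, dps=50) - 1.0) <= 1e-6
        for prior in NORMAL_GRID:
            assert abs(delta_elpd_normal(prior, 1e10, dps=50) - 1.0) <= 1e-6

    def test_induction_limit_is_b(self):
        for prior in (BetaPrior(1, 1), BetaPrior(0.5, 0.5), BetaPrior(2, 5)):
            got = delta_elpd_induction(prior, 1e12, dps=50)
            assert got == pytest.approx(prior.b, abs=1e-6)


class TestNumericalBehaviour:
    def test_double_precision_stable_at_huge_n(self):
        # log1p formulation keeps full accuracy far beyond where the naive
        # ratio evaluation would collapse to log(1) = 0
        assert delta_elpd_induction(BetaPrior(1, 1), 1e12) == pytest.approx(1.0, abs=1e-10)
        assert delta_elpd_chance(BetaPrior(1, 5), 1e12) == pytest.approx(1.0, abs=1e-9)
        assert delta_elpd_normal(NormalMeanPrior(9.0), 1e12) == pytest.approx(1.0, abs=1e-10)

    def test_double_agrees_with_high_precision(self):
        for n in (10.0, 1e4, 1e8):
            a = delta_elpd_chance(BetaPrior(1, 5), n)
            b = delta_elpd_chance(BetaPrior(1, 5), n, dps=60)
            assert a == pytest.approx(b, rel=1e-12)

    def test_real_valued_n_accepted(self):
        # smooth continuation in n, used by the extremum search
        mid = delta_elpd_normal(NormalMeanPrior(1.0), 2.5)
        lo = delta_elpd_normal(NormalMeanPrior(1.0), 2.0)
        hi = delta_elpd_normal(NormalMeanPrior(1.0), 3.0)
        assert lo < mid < hi

    def test_chance_rejects_odd_integer_n(self):
        with pytest.raises(ValueError, match="even"):
            delta_elpd_chance(BetaPrior(1, 1), 3)
        with pytest.raises(ValueError, match="even"):
            elpd_h1_chance(BetaPrior(1, 1), 5)


class TestMleLoo:
    @pytest.mark.parametrize("n", [2, 100, 10_000])
    def test_mle_loo_completely_uninformative(self, n):
        # every training fold yields the MLE theta-hat = 1, identical to the
        # null; both models predict the held-out success perfectly
        assert mle_loo_induction(n) == 0.0

    def test_needs_a_training_fold(self):
        with pytest.raises(ValueError):
            mle_loo_induction(1)
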