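"""Patient-mix distributions: densities, moments, fitting, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from racusum import (
    BetaBinomialMix,
    BetaMix,
    DiscretizedBetaMix,
    EstimationError,
    beta_cdf,
    beta_pdf,
    betabinomial_pmf,
    expected_score,
    median_score,
    mom_fit_beta,
    mom_fit_betabinomial,
    rescale_scores,
    sample_scores,
)
from racusum.patient_mix import (
    MomentEstimates,
    mom_fit_beta_from_moments,
    mom_fit_betabinomial_from_moments,
)

PHASE1 = (0.59, 4.12)
BETA_PHASE1 = (0.61, 4.09)


class TestBetaDensity:
    def test_uniform_special_case(self):
        assert beta_pdf(0.5, BetaMix(1, 1)) == pytest.approx(1.0)
        assert beta_cdf(0.5, BetaMix(1, 1)) == pytest.approx(0.5)

    def test_hand_evaluated_point(self):
        # B(2,2) = 1/6, so f(0.5) = 0.25 / (1/6) = 1.5
        assert beta_pdf(0.5, BetaMix(2, 2)) == pytest.approx(1.5, abs=1e-12)

    def test_pdf_normalizes_by_quadrature(self):
        mix = BetaMix(*BETA_PHASE1)
        total, _ = quad(lambda x: beta_pdf(x, mix), 0, 1, limit=200)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_cdf_matches_integrated_pdf(self):
        mix = BetaMix(*BETA_PHASE1)
        val, _ = quad(lambda x: beta_pdf(x, mix), 0, 0.3, limit=200)
        assert beta_cdf(0.3, mix) == pytest.approx(val, abs=1e-9)

    def test_cdf_endpoints(self):
        mix = BetaMix(2.3, 0.7)
        assert beta_cdf(0.0, mix) == 0.0
        assert beta_cdf(1.0, mix) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            beta_pdf(1.5, BetaMix(1, 1))
        with pytest.raises(ValueError):
            BetaMix(-1, 2)


class TestRescaling:
    def test_interval_midpoints(self):
        out = rescale_scores([0, 71], 71)
        assert out[0] == pytest.approx(0.5 / 72)
        assert out[1] == pytest.approx(71.5 / 72)

    def test_empty_input(self):
        assert len(rescale_scores([], 71)) == 0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rescale_scores([72], 71)


class TestMethodOfMoments:
    def test_beta_population_roundtrip(self):
        # population moments of beta(a, b) fed back into the estimator
        a, b = BETA_PHASE1
        m1 = a / (a + b)
        m2 = a * (a + 1) / ((a + b) * (a + b + 1))
        fit = mom_fit_beta_from_moments(MomentEstimates(m1, m2, 10))
        assert fit.alpha == pytest.approx(a, rel=1e-10)
        assert fit.beta == pytest.approx(b, rel=1e-10)

    def test_betabinomial_population_roundtrip(self):
        a, b = PHASE1
        n = 71
        m1 = n * a / (a + b)
        m2 = n * a * (n * (1 + a) + b) / ((a + b) * (a + b + 1))
        fit = mom_fit_betabinomial_from_moments(MomentEstimates(m1, m2, 10), n=n)
        assert fit.alpha == pytest.approx(a, rel=1e-10)
        assert fit.beta == pytest.approx(b, rel=1e-10)

    def test_beta_parameter_recovery_from_sample(self):
        # scores from the discretized beta, rescaled, refit: within 5%
        mix = DiscretizedBetaMix(*BETA_PHASE1, ncat=72)
        scores = sample_scores(mix, 100_000, seed=7)
        fit = mom_fit_beta(scores, smax=71)
        assert fit.alpha == pytest.approx(BETA_PHASE1[0], rel=0.05)
        assert fit.beta == pytest.approx(BETA_PHASE1[1], rel=0.05)

    def test_betabinomial_parameter_recovery_from_sample(self):
        mix = BetaBinomialMix(71, *PHASE1)
        scores = sample_scores(mix, 100_000, seed=11)
        fit = mom_fit_betabinomial(scores, n=71)
        assert fit.alpha == pytest.approx(PHASE1[0], rel=0.05)
        assert fit.beta == pytest.approx(PHASE1[1], rel=0.05)

    @pytest.mark.parametrize("fitter", [mom_fit_beta, mom_fit_betabinomial])
    def test_zero_variance_rejected(self, fitter):
        with pytest.raises(EstimationError):
            fitter([5] * 100)


class TestBetaBinomial:
    def test_uniform_special_case(self):
        mix = BetaBinomialMix(71, 1, 1)
        assert betabinomial_pmf(13, mix) == pytest.approx(1 / 72, abs=1e-14)

    def test_hand_evaluated_point(self):
        # C(2,1) B(3,3)/B(2,2) = 2 * (1/30)/(1/6) = 0.4
        assert betabinomial_pmf(1, BetaBinomialMix(2, 2, 2)) == pytest.approx(0.4, abs=1e-12)

    def test_pmf_sums_to_one(self, phase1_mix):
        assert phase1_mix.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_support(self, phase1_mix):
        with pytest.raises(ValueError):
            betabinomial_pmf(72, phase1_mix)


class TestSummaries:
    @pytest.mark.parametrize(
        "params, mean_1dp",
        [((1.50, 4.00), 19.4), ((0.92, 4.32), 12.5), ((1, 1), 35.5)],
    )
    def test_expected_score(self, params, mean_1dp):
        assert round(expected_score(BetaBinomialMix(71, *params)), 1) == mean_1dp

    @pytest.mark.parametrize(
        "params, med", [((0.59, 4.12), 5), ((1.50, 4.00), 17), ((1, 1), 35)]
    )
    def test_median_score(self, params, med):
        assert median_score(BetaBinomialMix(71, *params)) == med

    def test_median_rejects_continuous(self, beta_mix):
        with pytest.raises(TypeError):
            median_score(beta_mix)

    def test_discretized_and_betabinomial_agree_in_mean(self):
        # the two discrete models differ by the half-cell shift of the
        # discretization (~0.34 here), far below one score unit
        d = DiscretizedBetaMix(0.6, 4.1, ncat=72)
        bb = BetaBinomialMix(71, 0.6, 4.1)
        assert abs(d.mean_score() - bb.mean_score()) < 0.35


class TestSampling:
    def test_empty_draw(self, phase1_mix):
        assert len(sample_scores(phase1_mix, 0, seed=1)) == 0

    def test_seed_determinism(self, phase1_mix):
        a = sample_scores(phase1_mix, 1000, seed=42)
        b = sample_scores(phase1_mix, 1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_clt(self, phase1_mix):
        n = 100_000
        s = sample_scores(phase1_mix, n, seed=3)
        mu = phase1_mix.mean_score()
        sd = np.sqrt(phase1_mix.raw_moment2() - mu**2)
        assert abs(s.mean() - mu) < 3 * sd / np.sqrt(n)

    def test_continuous_beta_samples_on_unit_scale(self, beta_mix):
        x = sample_scores(beta_mix, 1000, seed=5)
        assert np.all((x >= 0) & (x <= 1))
        assert x.dtype == float


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.1, 10),
    beta=st.floats(0.1, 10),
    n=st.integers(2, 150),
)
def test_discrete_mixes_are_proper_distributions(alpha, beta, n):
    """Any admissible shape pair yields a pmf summing to 1 with a
    monotone CDF reaching 1 at the top of the support."""
    for mix in (BetaBinomialMix(n, alpha, beta), DiscretizedBetaMix(alpha, beta, ncat=n + 1)):
        assert mix.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(mix.probs >= 0)
        cdf = mix.cdf(np.arange(n + 1))
        assert np.all(np.diff(cdf) >= -1e-15)
        assert cdf[-1] == pytest.approx(1.0, abs=1e-12)
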