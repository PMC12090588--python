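"""Quantile fitting of expert judgements and linear opinion pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from priorelicit import (BetaPrior, ExpertElicitation, ExpertJudgement,
                         NormalPrior, fit_beta_to_quantiles,
                         fit_normal_to_quantiles, linear_pool)
from priorelicit.elicitation import (DegenerateScaleError, InvalidJudgementError)

QUARTILES = (0.25, 0.5, 0.75)
# standard-normal quartiles, from an independent quantile routine
Z25 = -0.6744897501960817

# Beta(2,2) quartiles frozen from an independent incomplete-beta inversion
BETA22_QUARTILES = (0.3263518223330697, 0.5, 0.6736481776669303)
# Beta(10.519, 5.181): the consensus control prior reconstructed from its
# published mean (0.67) and ESS (15.7) via alpha = mean * ESS
CONSENSUS_QUARTILES = (0.5936482168265865, 0.6773809815398852,
                       0.7540501271194362)


def judgement(values, quantity="control_response_rate", probs=QUARTILES):
    return ExpertJudgement("e1", quantity, probs, tuple(values))


class TestBetaFit:
    def test_recovers_symmetric_beta_from_exact_quartiles(self):
        fit = fit_beta_to_quantiles(judgement(BETA22_QUARTILES))
        assert fit.alpha == pytest.approx(2.0, abs=1e-3)
        assert fit.beta == pytest.approx(2.0, abs=1e-3)

    def test_recovers_consensus_hyperparameters(self):
        fit = fit_beta_to_quantiles(judgement(CONSENSUS_QUARTILES))
        assert fit.alpha == pytest.approx(10.519, rel=1e-2)
        assert fit.beta == pytest.approx(5.181, rel=1e-2)

    def test_symmetric_judgement_has_median_half(self):
        # a median-only expert padded with symmetric quartiles about 0.5
        fit = fit_beta_to_quantiles(judgement((0.35, 0.5, 0.65)))
        assert stats.beta.ppf(0.5, fit.alpha, fit.beta) == pytest.approx(0.5,
                                                                         abs=1e-6)
        assert fit.alpha == pytest.approx(fit.beta, rel=1e-4)

    def test_rejects_wrong_quantity(self):
        with pytest.raises(InvalidJudgementError):
            fit_beta_to_quantiles(judgement((-1.0, 0.0, 1.0),
                                            quantity="log_odds_ratio"))

    def test_rejects_repeated_values_as_point_mass(self):
        with pytest.raises(DegenerateScaleError):
            fit_beta_to_quantiles(judgement((0.5, 0.5, 0.6)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.5, 50), beta=st.floats(0.5, 50))
    def test_round_trip_recovers_hyperparameters(self, alpha, beta):
        levels = (0.05, 0.25, 0.5, 0.75, 0.95)
        values = stats.beta.ppf(levels, alpha, beta)
        fit = fit_beta_to_quantiles(
            ExpertJudgement("e", "control_response_rate", levels, tuple(values)))
        assert fit.alpha == pytest.approx(alpha, rel=1e-2)
        assert fit.beta == pytest.approx(beta, rel=1e-2)


class TestNormalFit:
    def test_standard_normal_from_quartiles(self):
        fit = fit_normal_to_quantiles(judgement(
            (Z25, -Z25), quantity="log_odds_ratio", probs=(0.25, 0.75)))
        assert fit.mu == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma == pytest.approx(1.0, abs=1e-6)

    def test_location_equivariance(self):
        shift = 1.3
        base = fit_normal_to_quantiles(judgement(
            (Z25, 0.0, -Z25), quantity="log_odds_ratio"))
        moved = fit_normal_to_quantiles(judgement(
            (Z25 + shift, shift, -Z25 + shift), quantity="log_odds_ratio"))
        assert moved.mu == pytest.approx(base.mu + shift, abs=1e-9)
        assert moved.sigma == pytest.approx(base.sigma, abs=1e-9)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            fit_normal_to_quantiles(judgement((0.2, 0.2, 0.2),
                                              quantity="log_odds_ratio"))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(mu=st.floats(-3, 3), sigma=st.floats(0.1, 3))
    def test_round_trip_exact(self, mu, sigma):
        levels = (0.05, 0.25, 0.5, 0.75, 0.95)
        values = stats.norm.ppf(levels, mu, sigma)
        fit = fit_normal_to_quantiles(
            ExpertJudgement("e", "log_odds_ratio", levels, tuple(values)))
        assert fit.mu == pytest.approx(mu, abs=1e-6)
        assert fit.sigma == pytest.approx(sigma, abs=1e-6)


class TestJudgementInvariants:
    @pytest.mark.parametrize("probs,values", [
        ((0.5, 0.25), (0.3, 0.5)),            # probs not increasing
        ((0.25, 0.75), (0.6, 0.4)),           # values decreasing
        ((0.5,), (0.5,)),                     # too few pairs
        ((0.25, 0.75), (0.0, 0.5)),           # rate quantile at boundary
        ((0.0, 0.75), (0.2, 0.5)),            # prob level at 0
    ])
    def test_invalid_judgements_rejected(self, probs, values):
        with pytest.raises(InvalidJudgementError):
            ExpertJudgement("e", "control_response_rate", probs, values)

    def test_dataframe_errors_report_rows(self):
        frame = pd.DataFrame({
            "expert_id": ["e1"] * 3, "quantity": ["control_response_rate"] * 3,
            "prob": [0.25, 0.5, 0.75], "value": [0.6, 0.5, 0.7]})
        with pytest.raises(InvalidJudgementError, match=r"rows \["):
            ExpertElicitation.from_dataframe(frame)


class TestLinearPool:
    def test_identical_components_pool_to_themselves(self):
        pool = linear_pool([BetaPrior(2, 2), BetaPrior(2, 2)])
        x = np.linspace(0.01, 0.99, 101)
        np.testing.assert_allclose(pool.pdf(x), BetaPrior(2, 2).pdf(x),
                                   atol=1e-10)

    def test_mirror_pair_has_mean_half(self):
        pool = linear_pool([BetaPrior(2, 8), BetaPrior(8, 2)])
        assert pool.mean() == pytest.approx(0.5, abs=1e-6)

    def test_pooled_mean_is_average_of_component_means(self, rng):
        components = [BetaPrior(a, b)
                      for a, b in rng.uniform(1, 20, size=(9, 2))]
        pool = linear_pool(components)
        expected = np.mean([c.mean for c in components])
        assert pool.mean() == pytest.approx(expected, abs=1e-5)

    def test_order_and_weight_scale_invariance(self):
        comps = [BetaPrior(2, 5), BetaPrior(6, 3), BetaPrior(1, 1)]
        x = np.linspace(0.01, 0.99, 51)
        a = linear_pool(comps, [1, 2, 3]).pdf(x)
        b = linear_pool(comps[::-1], [30, 20, 10]).pdf(x)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_pool_of_betas_is_a_density(self):
        grid = linear_pool([BetaPrior(2, 8), BetaPrior(8, 2),
                            BetaPrior(5, 5)]).to_grid(1024)
        assert np.all(grid.density >= 0)
        assert np.trapezoid(grid.density, grid.support) == pytest.approx(1.0,
                                                                         abs=1e-6)

    def test_empty_and_zero_weight_errors(self):
        with pytest.raises(ValueError):
            linear_pool([])
        with pytest.raises(ValueError):
            linear_pool([BetaPrior(2, 2)], [0.0])
        with pytest.raises(ValueError):
            linear_pool([BetaPrior(2, 2), NormalPrior(0, 1)])


class TestElicitationModel:
    def test_fit_produces_summary_per_expert(self):
        frame = pd.DataFrame([
            {"expert_id": "e1", "quantity": "control_response_rate",
             "prob": p, "value": v}
            for p, v in zip(QUARTILES, BETA22_QUARTILES)
        ] + [
            {"expert_id": "e1", "quantity": "log_odds_ratio",
             "prob": p, "value": v}
            for p, v in zip((0.25, 0.75), (Z25, -Z25))
        ])
        results = ExpertElicitation.from_dataframe(frame).fit()
        summary = results.summary()
        assert set(summary["family"]) == {"beta", "normal"}
        assert (summary["residual"] < 1e-6).all()
        assert "control_response_rate" in results.pooled
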