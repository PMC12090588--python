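"""Two-stage design: run-in gate, posterior updating, operating characteristics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from priorelicit import (BetaPrior, JointPrior, NormalPrior, TrialData,
                         TrialDesign, TwoArmBayesTrial, effective_sample_size,
                         joint_posterior, operating_characteristics,
                         runin_decision, uniform_joint_prior,
                         update_control_posterior)


def prior_predictive_oracle(joint, data, n=500_000, seed=7):
    """Brute-force sampler, independent of the grid code: draw from the prior,
    weight by the two binomial likelihoods, estimate P(theta > 0)."""
    rng = np.random.default_rng(seed)
    p = rng.beta(joint.control.alpha, joint.control.beta, n)
    t = rng.normal(joint.log_or.mu, joint.log_or.sigma, n)
    q = expit(logit(p) + t)
    (r1, n1), (r2, n2) = data.control, data.experimental
    w = (p ** r1 * (1 - p) ** (n1 - r1)) * (q ** r2 * (1 - q) ** (n2 - r2))
    return float(np.sum(w * (t > 0)) / np.sum(w))


class TestRunIn:
    @pytest.mark.parametrize("responders,expected", [
        (3, "proceed"), (2, "stop"), (0, "stop"), (10, "proceed"),
    ])
    def test_three_of_ten_gate(self, responders, expected, default_design):
        assert runin_decision(responders, default_design) == expected

    def test_monotone_in_responders(self, default_design):
        decisions = [runin_decision(r, default_design) for r in range(11)]
        assert decisions == sorted(decisions, key=lambda d: d == "proceed")

    def test_out_of_range_rejected(self, default_design):
        with pytest.raises(ValueError):
            runin_decision(11, default_design)


class TestConjugateUpdate:
    def test_no_data_is_identity(self):
        assert update_control_posterior(BetaPrior(1, 1), (0, 0)) == BetaPrior(1, 1)

    def test_consensus_update(self, consensus_ada):
        post = update_control_posterior(consensus_ada, (14, 20))
        assert post.alpha == pytest.approx(24.519)
        assert post.beta == pytest.approx(11.181)
        assert post.mean == pytest.approx(0.6868, abs=1e-4)

    def test_rule_of_succession(self):
        post = update_control_posterior(BetaPrior(1, 1), (7, 10))
        assert post.mean == pytest.approx(8 / 12)

    @pytest.mark.parametrize("r,n", [(0, 0), (5, 20), (20, 20)])
    def test_ess_additivity(self, consensus_ada, r, n):
        post = update_control_posterior(consensus_ada, (r, n))
        assert effective_sample_size(post) == pytest.approx(
            effective_sample_size(consensus_ada) + n)


class TestJointPosterior:
    def test_no_data_returns_prior(self):
        joint = JointPrior(BetaPrior(2, 2), NormalPrior(0.3, 0.7))
        post = joint_posterior(joint, TrialData((0, 0), (0, 0)))
        assert post.prob_superiority == pytest.approx(
            joint.log_or.prob_positive(), abs=1e-3)
        assert post.control.mean == pytest.approx(0.5, abs=1e-3)

    def test_symmetric_arms_give_half(self):
        joint = JointPrior(BetaPrior(2, 2), NormalPrior(0.0, 2.0))
        post = joint_posterior(joint, TrialData((10, 20), (10, 20)))
        assert post.prob_superiority == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force_oracle(self):
        joint = JointPrior(BetaPrior(2, 2), NormalPrior(0.0, 2.0))
        data = TrialData((8, 20), (14, 20))
        post = joint_posterior(joint, data)
        assert post.prob_superiority == pytest.approx(
            prior_predictive_oracle(joint, data), abs=0.01)

    @pytest.mark.parametrize("r,n", [(3, 10), (8, 20), (0, 5)])
    def test_flat_prior_reproduces_conjugate_mean(self, r, n):
        post = joint_posterior(uniform_joint_prior(), TrialData((r, n), (4, 10)))
        assert post.control.mean == pytest.approx((r + 1) / (n + 2), abs=0.005)

    def test_intervals_are_ordered_and_calibrated(self, consensus_joint):
        post = joint_posterior(consensus_joint, TrialData((14, 20), (11, 20)))
        for arm, (level, lo, hi) in post.intervals.items():
            assert 0 < lo < hi < 1
            assert level == 0.95


class TestOperatingCharacteristics:
    def test_zero_experimental_rate_always_stops(self, default_design):
        oc = operating_characteristics(default_design, "uniform", 0.5, 0.0,
                                       200, seed=1)
        assert oc.runin_stop_rate == 1.0
        assert oc.declare_rate == 0.0

    def test_null_scenario_rarely_declares(self, consensus_ada, default_design):
        joint = JointPrior(consensus_ada, NormalPrior(0.0, 1.0))
        oc = operating_characteristics(default_design, joint, 0.67, 0.67,
                                       500, seed=11)
        assert oc.declare_rate < 0.10

    def test_seed_determinism(self, default_design):
        a = operating_characteristics(default_design, "uniform", 0.5, 0.6,
                                      200, seed=5)
        b = operating_characteristics(default_design, "uniform", 0.5, 0.6,
                                      200, seed=5)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_declare_rate_monotone_in_experimental_rate(self, default_design):
        rates = []
        for p_exp in (0.4, 0.6, 0.8):
            oc = operating_characteristics(default_design, "uniform", 0.5,
                                           p_exp, 400, seed=9)
            rates.append((oc.declare_rate, oc.declare_se))
        for (lo_rate, lo_se), (hi_rate, hi_se) in zip(rates, rates[1:]):
            assert hi_rate >= lo_rate - 2 * np.hypot(lo_se, hi_se)

    def test_mc_standard_error_formula(self, default_design):
        oc = operating_characteristics(default_design, "uniform", 0.5, 0.7,
                                       300, seed=2)
        assert oc.declare_se == pytest.approx(
            np.sqrt(oc.declare_rate * (1 - oc.declare_rate) / 300))

    def test_small_n_sims_rejected(self, default_design):
        with pytest.raises(ValueError):
            operating_characteristics(default_design, "uniform", 0.5, 0.5,
                                      50, seed=1)


class TestModelInterface:
    def test_from_counts_fit_and_summary(self, consensus_joint):
        model = TwoArmBayesTrial.from_counts((14, 20), (11, 20), consensus_joint)
        results = model.fit()
        summary = results.summary()
        assert list(summary["arm"]) == ["ADA", "SEC"]
        assert 0 <= results.prob_superiority <= 1
        assert results.declares_superiority == (
            results.prob_superiority >= 0.95)

    def test_from_patients_aggregates_by_endpoint(self, consensus_joint):
        import pandas as pd
        frame = pd.DataFrame({
            "arm": ["ADA", "ADA", "SEC", "SEC"],
            "baseline_grade": [3, 1, 1, 2],
            "week12_grade": [1, 0.5, 0, 2],
        })
        model = TwoArmBayesTrial.from_patients(frame, consensus_joint)
        assert model.data.control == (1, 2)        # 3->1 responds, 1->0.5 not
        assert model.data.experimental == (1, 2)   # 1->0 responds, 2->2 not
        revised = TwoArmBayesTrial.from_patients(
            frame, consensus_joint, TrialDesign(endpoint="revised"))
        assert revised.data.control == (2, 2)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            TrialDesign(runin_threshold=11)
        with pytest.raises(ValueError):
            TrialDesign(endpoint="other")
        with pytest.raises(ValueError):
            TrialData((5, 3), (0, 0))
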