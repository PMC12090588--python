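"""Synthetic inputs: expert judgement sets with known truth and SUN-grade trials.

Everything downstream is testable without external data: expert quantile
judgements are generated around a known Beta/Normal ground truth (multiplicative
log-normal jitter, re-sorted, clipped to the support), and patient-level trial
datasets are built so the marginal responder probability under the chosen
endpoint equals the arm's true response rate exactly.  All generators are pure
functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elicitation import ExpertJudgement
from .priors import BetaPrior, NormalPrior
from .sun import ELIGIBLE_BASELINES, GRADES, classify_response

__all__ = ["ElicitationScenario", "TrialScenario",
           "gen_expert_judgements", "gen_trial_dataset"]

DEFAULT_PROB_LEVELS = (0.25, 0.5, 0.75)
#: default baseline-severity mix over grades 1+..4+ (mild disease most common)
DEFAULT_BASELINE_DIST = {1.0: 0.4, 2.0: 0.3, 3.0: 0.2, 4.0: 0.1}


@dataclass(frozen=True)
class ElicitationScenario:
    """Ground truth and noise model for a synthetic elicitation exercise."""

    true_control: BetaPrior
    true_log_or: NormalPrior
    n_experts: int = 9
    expert_noise: float = 0.05
    prob_levels: tuple[float, ...] = DEFAULT_PROB_LEVELS
    seed: int = 20231010

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError(f"n_experts must be >= 1, got {self.n_experts}")
        if self.expert_noise < 0:
            raise ValueError(f"expert_noise must be >= 0, got {self.expert_noise}")


@dataclass(frozen=True)
class TrialScenario:
    """True per-arm response probabilities and baseline severity mix."""

    true_control: float
    true_experimental: float
    control_n: int = 20
    experimental_n: int = 20
    baseline_dist: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_DIST))
    seed: int = 20231010

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_control <= 1.0
                and 0.0 <= self.true_experimental <= 1.0):
            raise ValueError("true response probabilities must be in [0, 1]")
        grades = sorted(self.baseline_dist)
        if 0.0 in grades:
            raise ValueError("baseline distribution must not put mass on grade 0 "
                             "(patients need active inflammation at entry)")
        if any(g not in ELIGIBLE_BASELINES for g in grades):
            raise ValueError(f"invalid baseline grades {grades}; must be drawn "
                             f"from {ELIGIBLE_BASELINES}")
        total = sum(self.baseline_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"baseline distribution must sum to 1, got {total}")


def gen_expert_judgements(scenario: ElicitationScenario) -> list[ExpertJudgement]:
    """Per-expert jittered quantiles of the true control-rate and log-OR priors.

    Each expert reports the truth's quantiles at ``prob_levels`` perturbed by
    multiplicative log-normal noise of scale ``expert_noise`` (log-OR values
    jittered additively on the same scale since they may be near zero), then
    re-sorted; response-rate quantiles are clipped to (0.001, 0.999).  With
    ``expert_noise = 0`` every expert reports the exact quantiles.
    """
    rng = np.random.default_rng(scenario.seed)
    levels = np.asarray(scenario.prob_levels)
    q_rate = scenario.true_control.ppf(levels)
    q_logor = scenario.true_log_or.ppf(levels)
    judgements = []
    for i in range(scenario.n_experts):
        expert = f"expert_{i + 1:02d}"
        jitter = np.exp(scenario.expert_noise * rng.standard_normal(levels.size))
        vals = np.sort(np.clip(q_rate * jitter, 0.001, 0.999))
        judgements.append(ExpertJudgement(
            expert, "control_response_rate", tuple(levels), tuple(vals)))
        shift = scenario.expert_noise * rng.standard_normal(levels.size)
        vals = np.sort(q_logor + shift)
        judgements.append(ExpertJudgement(
            expert, "log_odds_ratio", tuple(levels), tuple(vals)))
    return judgements


def judgements_to_frame(judgements: list[ExpertJudgement]) -> pd.DataFrame:
    """Long-format table (expert_id, quantity, prob, value) of judgements."""
    rows = [{"expert_id": j.expert_id, "quantity": j.quantity,
             "prob": p, "value": v}
            for j in judgements for p, v in zip(j.probs, j.values)]
    return pd.DataFrame(rows)


def _compatible_grades(baseline: float, endpoint: str) -> tuple[list, list]:
    """Week-12 grades that do / do not satisfy the endpoint for this baseline."""
    yes = [g for g in GRADES if classify_response(baseline, g, endpoint)]
    no = [g for g in GRADES if not classify_response(baseline, g, endpoint)]
    return yes, no


def gen_trial_dataset(scenario: TrialScenario,
                      endpoint: str = "original") -> pd.DataFrame:
    """Patient-level dataset whose responder probability matches the scenario.

    Each patient draws a baseline grade from the severity mix; with probability
    equal to the arm's true response rate the week-12 grade is uniform over the
    grades satisfying the endpoint given that baseline, otherwise uniform over
    those violating it — so classification recovers the true rate exactly in
    expectation, for either endpoint.
    """
    rng = np.random.default_rng(scenario.seed)
    grades = np.array(sorted(scenario.baseline_dist))
    probs = np.array([scenario.baseline_dist[g] for g in grades])
    compat = {g: _compatible_grades(g, endpoint) for g in grades}

    rows = []
    arms = [("ADA", scenario.control_n, scenario.true_control),
            ("SEC", scenario.experimental_n, scenario.true_experimental)]
    pid = 0
    for arm, n, p_resp in arms:
        baselines = rng.choice(grades, size=n, p=probs)
        responds = rng.random(n) < p_resp
        for b, resp in zip(baselines, responds):
            pool = compat[b][0] if resp else compat[b][1]
            week12 = pool[rng.integers(len(pool))]
            pid += 1
            rows.append({"patient_id": f"P{pid:04d}", "arm": arm,
                         "baseline_grade": float(b), "week12_grade": float(week12)})
    return pd.DataFrame(rows)
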