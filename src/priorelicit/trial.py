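"""Two-stage Bayesian phase II design: run-in gate, posterior, operating characteristics.

The design has a 10-patient single-arm run-in on the experimental treatment
(proceed to randomisation iff at least 3 respond), followed by a 20-per-arm
randomised stage analysed with the elicited joint prior: Beta on the control
response rate p_C, Normal on the log odds ratio theta, with
p_E = expit(logit(p_C) + theta).  Superiority is declared when the posterior
probability of theta > 0 reaches a configurable cutoff (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, xlogy

from .priors import (BetaPrior, DensityGrid, JointPrior, NormalPrior,
                     beta_approximation, beta_approximation_from_moments, moments)
from .sun import ENDPOINTS, classify_response

__all__ = [
    "TrialDesign",
    "TrialData",
    "PosteriorSummary",
    "OCResult",
    "runin_decision",
    "update_control_posterior",
    "joint_posterior",
    "operating_characteristics",
    "uniform_joint_prior",
    "TwoArmBayesTrial",
    "TrialResults",
]

CONTROL_ARM = "ADA"
EXPERIMENTAL_ARM = "SEC"


@dataclass(frozen=True)
class TrialDesign:
    """Two-stage design constants."""

    runin_n: int = 10
    runin_threshold: int = 3
    arm_n: int = 20
    endpoint: str = "original"
    superiority_cutoff: float = 0.95
    grid_size: int = 256

    def __post_init__(self) -> None:
        if not 0 < self.runin_threshold <= self.runin_n:
            raise ValueError(f"need 0 < runin_threshold <= runin_n, got "
                             f"({self.runin_threshold}, {self.runin_n})")
        if self.arm_n < 1:
            raise ValueError(f"arm_n must be >= 1, got {self.arm_n}")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if not 0.0 < self.superiority_cutoff < 1.0:
            raise ValueError("superiority_cutoff must be in (0, 1)")


@dataclass(frozen=True)
class TrialData:
    """Per-arm responder counts (r, n), optionally backed by patient records."""

    control: tuple[int, int]
    experimental: tuple[int, int]
    patients: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for arm, (r, n) in (("control", self.control),
                            ("experimental", self.experimental)):
            if not (0 <= r <= n):
                raise ValueError(f"{arm} arm needs 0 <= responders <= n, "
                                 f"got ({r}, {n})")

    @classmethod
    def from_patients(cls, frame: pd.DataFrame,
                      endpoint: str = "original") -> "TrialData":
        """Aggregate patient-level records (arm, baseline_grade, week12_grade)."""
        required = {"arm", "baseline_grade", "week12_grade"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"patient table is missing columns {sorted(missing)}")
        counts = {}
        for arm_label, grp in frame.groupby("arm"):
            resp = sum(classify_response(b, w, endpoint)
                       for b, w in zip(grp["baseline_grade"], grp["week12_grade"]))
            counts[str(arm_label)] = (int(resp), len(grp))
        for arm in (CONTROL_ARM, EXPERIMENTAL_ARM):
            if arm not in counts:
                raise ValueError(f"arm {arm!r} absent from patient table "
                                 f"(found {sorted(counts)})")
        return cls(counts[CONTROL_ARM], counts[EXPERIMENTAL_ARM], frame)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summaries of the two-arm model."""

    control: BetaPrior                     # moment-matched control marginal
    experimental: DensityGrid              # experimental-arm marginal
    prob_superiority: float
    intervals: dict                        # arm -> (level, lower, upper)
    control_grid: DensityGrid = field(repr=False, default=None)
    theta_grid: tuple = field(repr=False, default=None)


@dataclass(frozen=True)
class OCResult:
    """Operating characteristics of one simulated scenario."""

    true_control: float
    true_experimental: float
    n_sims: int
    declare_rate: float
    declare_se: float
    runin_stop_rate: float
    prior_variant: str
    seed: int


def runin_decision(responders: int, design: TrialDesign) -> str:
    """Run-in gate: ``"proceed"`` iff responders >= the threshold (default 3/10)."""
    if not 0 <= responders <= design.runin_n:
        raise ValueError(f"responders must be in [0, {design.runin_n}], "
                         f"got {responders}")
    return "proceed" if responders >= design.runin_threshold else "stop"


def update_control_posterior(prior: BetaPrior, data: tuple[int, int]) -> BetaPrior:
    """Conjugate beta-binomial update: Beta(a+r, b+n-r).  ESS grows by n."""
    r, n = data
    return prior.update(r, n)


def uniform_joint_prior(theta_sigma: float = 10.0) -> JointPrior:
    """Weakly-informative reference prior: Beta(1,1) and a wide Normal on theta."""
    return JointPrior(BetaPrior(1.0, 1.0), NormalPrior(0.0, theta_sigma))


# ---------------------------------------------------------------------------
# posterior computation (deterministic 2-D grid)

def _theta_range(joint: JointPrior, data: TrialData) -> tuple[float, float]:
    """Range covering both the prior and the likelihood-supported theta values."""
    mu, sigma = joint.log_or.mu, joint.log_or.sigma
    (r1, n1), (r2, n2) = data.control, data.experimental
    lo, hi = mu - 8 * sigma, mu + 8 * sigma
    if n1 > 0 and n2 > 0:
        # continuity-corrected MLE and its asymptotic s.e.
        theta_hat = (np.log((r2 + 0.5) / (n2 - r2 + 0.5))
                     - np.log((r1 + 0.5) / (n1 - r1 + 0.5)))
        se = np.sqrt(1 / (r1 + 0.5) + 1 / (n1 - r1 + 0.5)
                     + 1 / (r2 + 0.5) + 1 / (n2 - r2 + 0.5))
        prec = 1 / sigma**2 + 1 / se**2
        m = (mu / sigma**2 + theta_hat / se**2) / prec
        s = 1 / np.sqrt(prec)
        lo = min(m - 8 * s, mu - 2 * sigma)
        hi = max(m + 8 * s, mu + 2 * sigma)
    return min(lo, -0.5), max(hi, 0.5)


def _log_joint_density(joint: JointPrior, data: TrialData,
                       p: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Unnormalised log posterior on the (p, theta) tensor grid."""
    a, b = joint.control.alpha, joint.control.beta
    (r1, n1), (r2, n2) = data.control, data.experimental
    lp = ((a - 1 + r1) * np.log(p) + (b - 1 + n1 - r1) * np.log1p(-p))[:, None]
    lt = stats.norm.logpdf(theta, joint.log_or.mu, joint.log_or.sigma)[None, :]
    q = expit(logit(p)[:, None] + theta[None, :])
    lq = xlogy(r2, q) + xlogy(n2 - r2, 1.0 - q)
    return lp + lt + lq


def joint_posterior(joint: JointPrior, data: TrialData,
                    grid_size: int = 256, level: float = 0.95) -> PosteriorSummary:
    """Posterior over (p_control, theta) given binomial data in both arms.

    Computed on a ``grid_size x grid_size`` tensor grid: beta-quantile-spaced
    points in p (quantiles of the conjugate control-arm update, which brackets
    the true marginal) and a uniform theta grid containing 0 over a range
    covering prior and likelihood.  All integrals use the trapezoid rule;
    ``prob_superiority`` is the posterior mass of theta > 0.
    """
    (r1, n1), (r2, n2) = data.control, data.experimental
    conj = joint.control.update(r1, n1)
    levels = np.linspace(1e-6, 1 - 1e-6, grid_size)
    p = np.clip(conj.ppf(levels), 1e-12, 1 - 1e-12)

    t_lo, t_hi = _theta_range(joint, data)
    theta = np.union1d(np.linspace(t_lo, t_hi, grid_size), [0.0])

    logpost = _log_joint_density(joint, data, p, theta)
    logpost -= logpost.max()
    post = np.exp(logpost)
    total = np.trapezoid(np.trapezoid(post, theta, axis=1), p)
    if not (np.isfinite(total) and total > 0):
        raise ArithmeticError("posterior has zero or non-finite mass on the grid; "
                              f"grid p in [{p[0]:.2e}, {1 - p[-1]:.2e}], "
                              f"theta in [{t_lo:.2f}, {t_hi:.2f}]")
    post /= total

    # theta marginal and superiority mass (0 is a grid node)
    g_theta = np.trapezoid(post, p, axis=0)
    pos = theta >= 0.0
    prob_sup = float(np.trapezoid(g_theta[pos], theta[pos])
                     / np.trapezoid(g_theta, theta))

    # control marginal
    h_p = np.trapezoid(post, theta, axis=1)
    control_grid = DensityGrid.from_values(p, h_p, {"construction": "posterior_control"})
    control_beta = beta_approximation(control_grid)

    experimental = _experimental_marginal(joint, data, grid_size)

    intervals = {
        "control": (level, *control_grid.interval(level)),
        "experimental": (level, *experimental.interval(level)),
    }
    return PosteriorSummary(control_beta, experimental, prob_sup, intervals,
                            control_grid, (theta, g_theta))


def _experimental_marginal(joint: JointPrior, data: TrialData,
                           grid_size: int) -> DensityGrid:
    """Posterior marginal of p_experimental on a beta-quantile-spaced q grid."""
    (r1, n1), (r2, n2) = data.control, data.experimental
    conj = joint.control.update(r1, n1)
    levels = np.linspace(1e-6, 1 - 1e-6, grid_size)
    p = np.clip(conj.ppf(levels), 1e-12, 1 - 1e-12)

    # q grid: quantiles of a rough conjugate-style beta for the experimental arm
    prior_mean = expit(logit(joint.control.mean) + joint.log_or.mu)
    rough = beta_approximation_from_moments(
        prior_mean, min(0.5 * prior_mean * (1 - prior_mean),
                        joint.control.variance + joint.log_or.sigma ** 2 / 16))
    q = np.clip(rough.update(r2, n2).ppf(levels), 1e-12, 1 - 1e-12)

    # density of q: integrate the joint over p at theta = logit(q) - logit(p)
    theta_q = logit(q)[None, :] - logit(p)[:, None]
    a, b = joint.control.alpha, joint.control.beta
    lp = ((a - 1 + r1) * np.log(p) + (b - 1 + n1 - r1) * np.log1p(-p))[:, None]
    lt = stats.norm.logpdf(theta_q, joint.log_or.mu, joint.log_or.sigma)
    lq = (xlogy(r2, q) + xlogy(n2 - r2, 1.0 - q) - np.log(q * (1.0 - q)))[None, :]
    ln = lp + lt + lq
    ln -= ln.max()
    dens = np.trapezoid(np.exp(ln), p, axis=0)
    return DensityGrid.from_values(q, dens,
                                   {"construction": "posterior_experimental"})


# ---------------------------------------------------------------------------
# operating characteristics

def operating_characteristics(design: TrialDesign, joint, true_control: float,
                              true_experimental: float, n_sims: int,
                              seed: int) -> OCResult:
    """Simulate the two-stage design and estimate its frequentist properties.

    Each replicate draws the run-in responder count (binomial at the true
    experimental rate), applies the stop/go gate, and — conditional on
    proceeding — draws both randomised arms and applies the posterior
    superiority rule.  ``joint`` may be a :class:`JointPrior` or the string
    ``"uniform"`` for the Beta(1,1) x Normal(0,10) reference prior.
    Stopped trials count as non-declarations.
    """
    if n_sims < 100:
        raise ValueError(f"n_sims must be >= 100, got {n_sims}")
    if not (0.0 <= true_control <= 1.0 and 0.0 <= true_experimental <= 1.0):
        raise ValueError("true rates must be in [0, 1]")
    variant = "uniform" if isinstance(joint, str) else "informative"
    if isinstance(joint, str):
        if joint != "uniform":
            raise ValueError(f"unknown prior variant {joint!r}")
        joint = uniform_joint_prior()

    rng = np.random.default_rng(seed)
    runin = rng.binomial(design.runin_n, true_experimental, size=n_sims)
    proceed = runin >= design.runin_threshold
    r_ctrl = rng.binomial(design.arm_n, true_control, size=n_sims)
    r_exp = rng.binomial(design.arm_n, true_experimental, size=n_sims)

    # the declare decision is a deterministic function of the responder counts
    decision_cache: dict[tuple[int, int], bool] = {}

    def declares(rc: int, re: int) -> bool:
        key = (rc, re)
        if key not in decision_cache:
            post = joint_posterior(
                joint, TrialData((rc, design.arm_n), (re, design.arm_n)),
                grid_size=design.grid_size)
            decision_cache[key] = post.prob_superiority >= design.superiority_cutoff
        return decision_cache[key]

    declared = np.array([proceed[i] and declares(int(r_ctrl[i]), int(r_exp[i]))
                         for i in range(n_sims)])
    rate = float(declared.mean())
    return OCResult(
        true_control=float(true_control),
        true_experimental=float(true_experimental),
        n_sims=n_sims,
        declare_rate=rate,
        declare_se=float(np.sqrt(rate * (1.0 - rate) / n_sims)),
        runin_stop_rate=float((~proceed).mean()),
        prior_variant=variant,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# model / results

class TwoArmBayesTrial:
    """Bayesian two-arm binomial trial model with an elicited joint prior.

    Built from per-arm responder counts (``from_counts``) or patient-level
    SUN-grade records (``from_patients``); ``fit()`` computes the posterior
    on a deterministic grid and returns a :class:`TrialResults`.
    """

    def __init__(self, data: TrialData, prior: JointPrior,
                 design: TrialDesign | None = None):
        self.data = data
        self.prior = prior
        self.design = design or TrialDesign()

    @classmethod
    def from_counts(cls, control: tuple[int, int], experimental: tuple[int, int],
                    prior: JointPrior, design: TrialDesign | None = None):
        return cls(TrialData(tuple(control), tuple(experimental)), prior, design)

    @classmethod
    def from_patients(cls, frame: pd.DataFrame, prior: JointPrior,
                      design: TrialDesign | None = None):
        design = design or TrialDesign()
        return cls(TrialData.from_patients(frame, design.endpoint), prior, design)

    def fit(self, grid_size: int | None = None, level: float = 0.95
            ) -> "TrialResults":
        summary = joint_posterior(self.prior, self.data,
                                  grid_size=grid_size or self.design.grid_size,
                                  level=level)
        return TrialResults(self, summary, level)

    def simulate(self, true_control: float, true_experimental: float,
                 n_sims: int = 2000, seed: int = 0,
                 prior_variant: str = "informative") -> OCResult:
        joint = self.prior if prior_variant == "informative" else "uniform"
        return operating_characteristics(self.design, joint, true_control,
                                         true_experimental, n_sims, seed)


@dataclass
class TrialResults:
    """Posterior estimates, intervals and the design decision."""

    model: TwoArmBayesTrial
    posterior: PosteriorSummary
    level: float = 0.95

    @property
    def prob_superiority(self) -> float:
        return self.posterior.prob_superiority

    @property
    def declares_superiority(self) -> bool:
        return self.prob_superiority >= self.model.design.superiority_cutoff

    def summary(self) -> pd.DataFrame:
        """One row per arm: posterior mean, credible interval, data."""
        post = self.posterior
        exp_mean, _ = moments(post.experimental)
        lvl_c, lo_c, hi_c = post.intervals["control"]
        lvl_e, lo_e, hi_e = post.intervals["experimental"]
        data = self.model.data
        return pd.DataFrame([
            {"arm": CONTROL_ARM, "responders": data.control[0],
             "n": data.control[1], "posterior_mean": post.control.mean,
             "level": lvl_c, "lower": lo_c, "upper": hi_c},
            {"arm": EXPERIMENTAL_ARM, "responders": data.experimental[0],
             "n": data.experimental[1], "posterior_mean": exp_mean,
             "level": lvl_e, "lower": lo_e, "upper": hi_e},
        ])

    def plot(self, ax=None):
        """Posterior response-rate densities: control solid, experimental dashed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.posterior.control_grid
        ax.plot(grid.support, grid.density, "k-", label=CONTROL_ARM)
        exp = self.posterior.experimental
        ax.plot(exp.support, exp.density, "r--", label=EXPERIMENTAL_ARM)
        ax.set_xlabel("response rate")
        ax.set_ylabel("posterior density")
        ax.legend()
        return ax
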