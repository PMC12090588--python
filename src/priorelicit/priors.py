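"""Parametric priors for two-arm response rates and the derived experimental marginal.

The model: the control-arm response probability ``p_C`` carries a Beta(alpha, beta)
prior, the log odds ratio ``theta = log[p_E(1-p_C) / (p_C(1-p_E))]`` carries an
independent Normal(mu, sigma) prior, and the experimental-arm probability
``p_E = expit(logit(p_C) + theta)`` inherits its prior by pushforward.  That
marginal has no closed form; it is derived by quadrature onto a density grid and,
when a conjugate-style summary is wanted, moment-matched back to a beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit, roots_hermitenorm, roots_legendre

__all__ = [
    "BetaPrior",
    "NormalPrior",
    "JointPrior",
    "DensityGrid",
    "log_odds_ratio",
    "derive_experimental_marginal",
    "moments",
    "beta_approximation",
    "effective_sample_size",
    "solve_log_or_prior",
]


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior for a response probability."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"beta hyperparameters must be positive, got "
                             f"({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    @property
    def ess(self) -> float:
        """Effective sample size: the number of observations the prior is worth."""
        return self.alpha + self.beta

    def pdf(self, x):
        return stats.beta.pdf(x, self.alpha, self.beta)

    def ppf(self, q):
        return stats.beta.ppf(q, self.alpha, self.beta)

    def cdf(self, x):
        return stats.beta.cdf(x, self.alpha, self.beta)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        t = (1.0 - level) / 2.0
        return float(self.ppf(t)), float(self.ppf(1.0 - t))

    def update(self, responders: int, n: int) -> "BetaPrior":
        """Conjugate update with binomial data (r successes out of n)."""
        if not 0 <= responders <= n:
            raise ValueError(f"need 0 <= responders <= n, got ({responders}, {n})")
        return BetaPrior(self.alpha + responders, self.beta + n - responders)


@dataclass(frozen=True)
class NormalPrior:
    """Normal(mu, sigma) prior for the log odds ratio (log-odds units)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def pdf(self, x):
        return stats.norm.pdf(x, self.mu, self.sigma)

    def ppf(self, q):
        return stats.norm.ppf(q, self.mu, self.sigma)

    def prob_positive(self) -> float:
        """Prior probability that the experimental arm is superior (theta > 0)."""
        return float(stats.norm.sf(0.0, self.mu, self.sigma))


@dataclass(frozen=True)
class JointPrior:
    """Independent (BetaPrior on p_control) x (NormalPrior on log-OR)."""

    control: BetaPrior
    log_or: NormalPrior


@dataclass(frozen=True)
class DensityGrid:
    """Nonparametric density on (0, 1): strictly increasing support, values >= 0.

    The density is normalised so its trapezoid integral is one; ``metadata``
    records how the grid was built (operation, grid size, raw integral).
    """

    support: np.ndarray
    density: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "density", density)
        if support.ndim != 1 or support.shape != density.shape:
            raise ValueError("support and density must be 1-D arrays of equal length")
        if not (np.all(np.diff(support) > 0) and support[0] > 0 and support[-1] < 1):
            raise ValueError("support must be strictly increasing inside (0, 1)")
        if np.any(density < 0):
            raise ValueError("density values must be nonnegative")
        total = float(np.trapezoid(density, support))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 (got {total:.8f})")

    @classmethod
    def from_values(cls, support, density, metadata=None) -> "DensityGrid":
        """Build a grid, renormalising the raw density by its trapezoid integral."""
        support = np.asarray(support, dtype=float)
        density = np.asarray(density, dtype=float)
        raw = float(np.trapezoid(density, support))
        if not np.isfinite(raw) or raw <= 0:
            raise ArithmeticError(f"cannot normalise density with integral {raw}")
        meta = dict(metadata or {})
        meta.setdefault("raw_integral", raw)
        return cls(support, density / raw, meta)

    @classmethod
    def from_beta(cls, prior: BetaPrior, grid_size: int = 256) -> "DensityGrid":
        x = np.unique(np.clip(prior.ppf(_tail_refined_levels(grid_size)),
                              1e-12, 1 - 1e-12))
        return cls.from_values(x, prior.pdf(x),
                               {"construction": "beta", "alpha": prior.alpha,
                                "beta": prior.beta, "grid_size": grid_size})

    def cdf(self, x):
        """Trapezoid CDF of the grid density, evaluated by interpolation."""
        grid_cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.density[1:] + self.density[:-1]) * np.diff(self.support))])
        grid_cdf = grid_cdf / grid_cdf[-1]
        return np.interp(x, self.support, grid_cdf, left=0.0, right=1.0)

    def ppf(self, q):
        grid_cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.density[1:] + self.density[:-1]) * np.diff(self.support))])
        grid_cdf = grid_cdf / grid_cdf[-1]
        # make cdf strictly increasing for stable inversion
        grid_cdf = np.maximum.accumulate(grid_cdf + 1e-15 * np.arange(len(grid_cdf)))
        return np.interp(q, grid_cdf / grid_cdf[-1], self.support)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        t = (1.0 - level) / 2.0
        lo, hi = self.ppf([t, 1.0 - t])
        return float(lo), float(hi)


def _tail_refined_levels(grid_size: int, n_tail: int = 16) -> np.ndarray:
    """Quantile levels: uniform core with geometrically refined tails, so
    grids placed at these quantiles resolve the distribution's extremes."""
    tail = np.geomspace(1e-8, 0.01, n_tail + 1)[:-1]
    core = np.linspace(0.01, 0.99, grid_size - 2 * n_tail)
    return np.concatenate([tail, core, 1.0 - tail[::-1]])


def log_odds_ratio(p_control: float, p_experimental: float) -> float:
    """Log odds ratio of the experimental arm relative to control.

    Returns ``log[p_E(1-p_C) / (p_C(1-p_E))]``; positive values mean the
    experimental arm is superior.  Both probabilities must lie strictly in (0, 1).
    """
    p_c = float(p_control)
    p_e = float(p_experimental)
    if not (0.0 < p_c < 1.0 and 0.0 < p_e < 1.0):
        raise ValueError(
            f"probabilities must be strictly inside (0, 1), got ({p_c}, {p_e})")
    return float(logit(p_e) - logit(p_c))


def effective_sample_size(prior: BetaPrior) -> float:
    """ESS of a beta prior: the sum of its hyperparameters, alpha + beta."""
    return float(prior.alpha + prior.beta)


def derive_experimental_marginal(joint: JointPrior, grid_size: int = 256,
                                 n_quad: int = 512) -> DensityGrid:
    """Marginal prior density of the experimental response rate, by quadrature.

    For each grid point q the density is the pushforward of
    ``p_E = expit(logit(p_C) + theta)``:

        f(q) = 1/(q(1-q)) * int f_normal(t) f_beta(p(t)) p(t)(1-p(t)) dt,

    with ``p(t) = expit(logit(q) - t)`` — the integral over p rewritten in
    theta, so Gauss-Hermite nodes centred on the Normal prior compute it
    accurately for any sigma, including the sigma -> 0 delta limit.  The
    evaluation grid sits at quantiles of a moment-matched beta, with
    geometrically refined tail levels, so the marginal's tails are resolved.
    """
    if grid_size < 64:
        raise ValueError("grid_size must be at least 64")
    control, log_or = joint.control, joint.log_or

    # Gauss-Hermite nodes in theta (probabilists' weights sum to 1)
    h_nodes, h_weights = roots_hermitenorm(n_quad)
    h_weights = h_weights / np.sqrt(2.0 * np.pi)
    theta = log_or.mu + log_or.sigma * h_nodes

    # approximate pushforward moments for grid placement (Gauss-Legendre in u)
    nodes, weights = roots_legendre(256)
    u = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    logit_p = logit(np.clip(control.ppf(u), 1e-300, 1 - 1e-16))
    q2d = expit(logit_p[:, None] + theta[None, :])
    w2d = w[:, None] * h_weights[None, :]
    m = float(np.sum(w2d * q2d))
    v = float(np.sum(w2d * (q2d - m) ** 2))
    ref = beta_approximation_from_moments(m, v) if v < m * (1 - m) else BetaPrior(1, 1)

    grid = np.unique(np.clip(ref.ppf(_tail_refined_levels(grid_size)),
                             1e-12, 1 - 1e-12))

    p_t = expit(logit(grid)[:, None] - theta[None, :])
    integrand = control.pdf(p_t) * p_t * (1.0 - p_t)
    dens = integrand @ h_weights / (grid * (1.0 - grid))
    if not np.all(np.isfinite(dens)):
        raise ArithmeticError("quadrature produced non-finite density values")
    return DensityGrid.from_values(grid, dens, {
        "construction": "derive_experimental_marginal",
        "grid_size": grid_size, "n_quad": n_quad,
        "control": (control.alpha, control.beta),
        "log_or": (log_or.mu, log_or.sigma),
    })


def solve_log_or_prior(control: BetaPrior, target: BetaPrior,
                       n_quad: int = 128) -> NormalPrior:
    """Normal log-OR prior making the derived experimental marginal match a beta.

    The published summaries pin down the two arms' beta priors but not the
    Normal(mu, sigma) prior on the log odds ratio that produced the
    experimental marginal; this inverts that construction, solving the two
    moment equations  mean(pushforward) = target mean  and
    var(pushforward) = target variance  by quadrature and a damped root find.
    """
    nodes, weights = roots_legendre(n_quad)
    u = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    logit_p = logit(np.clip(control.ppf(u), 1e-300, 1 - 1e-16))
    h_nodes, h_weights = roots_hermitenorm(n_quad)
    h_weights = h_weights / np.sqrt(2.0 * np.pi)
    m_t, v_t = target.mean, target.variance

    def equations(x):
        mu, log_sigma = x
        theta = mu + np.exp(log_sigma) * h_nodes
        q = expit(logit_p[:, None] + theta[None, :])
        w2d = w[:, None] * h_weights[None, :]
        m = np.sum(w2d * q)
        v = np.sum(w2d * (q - m) ** 2)
        return [m - m_t, v - v_t]

    x0 = [float(logit(m_t) - logit(control.mean)), np.log(0.5)]
    sol = optimize.root(equations, x0, method="hybr", tol=1e-12)
    if not sol.success:
        raise ArithmeticError(f"log-OR prior solve failed: {sol.message}")
    return NormalPrior(float(sol.x[0]), float(np.exp(sol.x[1])))


def moments(density: DensityGrid) -> tuple[float, float]:
    """Trapezoid-rule mean and central variance of a density grid."""
    x, f = density.support, density.density
    mean = float(np.trapezoid(x * f, x))
    var = float(np.trapezoid((x - mean) ** 2 * f, x))
    return mean, var


def beta_approximation_from_moments(mean: float, variance: float) -> BetaPrior:
    """Moment-matched beta: k = m(1-m)/v - 1, alpha = m*k, beta = (1-m)*k."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0,1), got {mean}")
    if not 0.0 < variance < mean * (1.0 - mean):
        raise ValueError(
            f"variance {variance} not in (0, mean(1-mean)={mean*(1-mean)}); "
            "no beta distribution matches these moments")
    k = mean * (1.0 - mean) / variance - 1.0
    return BetaPrior(mean * k, (1.0 - mean) * k)


def beta_approximation(density: DensityGrid) -> BetaPrior:
    """Moment-matched beta approximation of a density grid on (0, 1)."""
    m, v = moments(density)
    return beta_approximation_from_moments(m, v)
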