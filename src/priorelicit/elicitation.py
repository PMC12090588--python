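"""Fit expert quantile judgements to parametric priors and pool across experts.

Each expert states a few quantiles of an uncertain quantity — the control-arm
response rate (a probability) or the log odds ratio of the experimental arm
versus control.  A Beta distribution is fitted to response-rate judgements and
a Normal to log-odds-ratio judgements by least squares on the stated quantiles.
When no behavioural consensus is available, the individual densities are
combined by a linear opinion pool (a weighted mixture, equal weights by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .priors import BetaPrior, DensityGrid, NormalPrior

__all__ = [
    "ExpertJudgement",
    "PooledDensity",
    "InvalidJudgementError",
    "DegenerateScaleError",
    "FitFailureError",
    "fit_beta_to_quantiles",
    "fit_normal_to_quantiles",
    "linear_pool",
    "ExpertElicitation",
    "ElicitationResults",
]

QUANTITIES = ("control_response_rate", "log_odds_ratio")


class InvalidJudgementError(ValueError):
    """A judgement violates the elicitation invariants (ordering, support...)."""


class DegenerateScaleError(InvalidJudgementError):
    """Identical quantile values at distinct probability levels: zero spread."""


class FitFailureError(RuntimeError):
    """The quantile fit did not converge; carries the residual diagnostics."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ExpertJudgement:
    """One expert's quantile statements about one elicited quantity.

    ``probs`` are strictly increasing cumulative probability levels in (0, 1);
    ``values`` are the stated quantiles (non-decreasing; inside (0, 1) when the
    quantity is a response rate).
    """

    expert_id: str
    quantity: str
    probs: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "values", values)
        if self.quantity not in QUANTITIES:
            raise InvalidJudgementError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}")
        if len(probs) != len(values) or len(probs) < 2:
            raise InvalidJudgementError(
                f"need >= 2 matching (prob, value) pairs, got "
                f"{len(probs)} probs and {len(values)} values")
        if not all(0.0 < p < 1.0 for p in probs):
            raise InvalidJudgementError(f"probability levels must be in (0,1): {probs}")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise InvalidJudgementError(f"probability levels must be strictly "
                                        f"increasing: {probs}")
        if any(b < a for a, b in zip(values, values[1:])):
            raise InvalidJudgementError(f"quantile values must be non-decreasing: "
                                        f"{values}")
        if self.quantity == "control_response_rate" and not all(
                0.0 < v < 1.0 for v in values):
            raise InvalidJudgementError(
                f"response-rate quantiles must lie strictly in (0,1): {values}")


# ---------------------------------------------------------------------------
# quantile fitting

_BETA_LOG_BOUNDS = (np.log(1e-3), np.log(1e4))
_FIT_TOL = 1e-10


def _beta_moment_start(probs: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    # crude mean from the interpolated median, spread from the widest pair
    m = float(np.interp(0.5, probs, values))
    m = min(max(m, 1e-3), 1 - 1e-3)
    z = stats.norm.ppf(probs)
    span = (values[-1] - values[0]) / max(z[-1] - z[0], 1e-6)
    v = max(span ** 2, 1e-8)
    v = min(v, 0.99 * m * (1 - m))
    k = m * (1 - m) / v - 1.0
    k = min(max(k, 0.1), 5e3)
    return m * k, (1 - m) * k


def fit_beta_to_quantiles(judgement: ExpertJudgement) -> BetaPrior:
    """Least-squares Beta(alpha, beta) fit to stated response-rate quantiles.

    Minimises the sum of squared differences between the stated quantiles and
    the beta quantile function at the stated probability levels, with
    multi-start bounded optimisation from method-of-moments initial values.
    """
    if judgement.quantity != "control_response_rate":
        raise InvalidJudgementError(
            f"beta fit requires a control_response_rate judgement, "
            f"got {judgement.quantity!r}")
    probs = np.asarray(judgement.probs)
    values = np.asarray(judgement.values)
    if np.any(np.diff(values) <= 0):
        raise DegenerateScaleError(
            f"expert {judgement.expert_id!r}: repeated quantile values {values} "
            "at distinct levels would imply a point mass")

    def residuals(x):
        a, b = np.exp(x)
        return stats.beta.ppf(probs, a, b) - values

    a0, b0 = _beta_moment_start(probs, values)
    starts = [(a0, b0)] + [(a0 * s, b0 * s) for s in (0.2, 5.0, 25.0)] + [(2.0, 2.0)]
    best = None
    for a_s, b_s in starts:
        x0 = np.clip(np.log([a_s, b_s]), *_BETA_LOG_BOUNDS)
        sol = optimize.least_squares(
            residuals, x0, bounds=_BETA_LOG_BOUNDS, xtol=1e-14, ftol=_FIT_TOL,
            gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    residual = float(np.sqrt(2.0 * best.cost))
    if not best.success:
        raise FitFailureError(
            f"beta quantile fit failed for expert {judgement.expert_id!r} "
            f"(status {best.status}, residual {residual:.3e})", residual)
    alpha, beta = np.exp(best.x)
    return BetaPrior(float(alpha), float(beta))


def fit_normal_to_quantiles(judgement: ExpertJudgement) -> NormalPrior:
    """Least-squares Normal(mu, sigma) fit to stated log-odds-ratio quantiles.

    The quantile function is linear in (mu, sigma) — ``Q(p) = mu + sigma z_p``
    with z_p the standard-normal quantile — so the least-squares solution is the
    ordinary regression of the stated values on z_p.
    """
    if judgement.quantity != "log_odds_ratio":
        raise InvalidJudgementError(
            f"normal fit requires a log_odds_ratio judgement, "
            f"got {judgement.quantity!r}")
    z = stats.norm.ppf(judgement.probs)
    v = np.asarray(judgement.values)
    if np.ptp(v) == 0.0:
        raise DegenerateScaleError(
            f"expert {judgement.expert_id!r}: identical values {v[0]} at distinct "
            "levels give zero scale")
    sigma = float(np.cov(z, v, bias=True)[0, 1] / np.var(z))
    mu = float(v.mean() - sigma * z.mean())
    if sigma <= 0:
        raise FitFailureError(
            f"expert {judgement.expert_id!r}: fitted scale {sigma} is not positive")
    return NormalPrior(mu, sigma)


def fit_judgement(judgement: ExpertJudgement) -> BetaPrior | NormalPrior:
    """Dispatch to the beta or normal quantile fit by elicited quantity."""
    if judgement.quantity == "control_response_rate":
        return fit_beta_to_quantiles(judgement)
    return fit_normal_to_quantiles(judgement)


# ---------------------------------------------------------------------------
# opinion pooling

@dataclass(frozen=True)
class PooledDensity:
    """Linear opinion pool: a weighted mixture of expert densities.

    ``components`` is a list of (weight, density) pairs whose weights are
    normalised to sum to one; ``support`` is the common support interval.
    """

    components: tuple
    support: tuple[float, float]

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, dens in self.components:
            out = out + w * dens.pdf(x)
        return out

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components])

    def mean(self, n_grid: int = 4001) -> float:
        lo, hi = self._finite_support()
        x = np.linspace(lo, hi, n_grid)
        f = self.pdf(x)
        return float(np.trapezoid(x * f, x) / np.trapezoid(f, x))

    def to_grid(self, grid_size: int = 512) -> DensityGrid:
        lo, hi = self._finite_support()
        x = np.linspace(lo, hi, grid_size)
        return DensityGrid.from_values(x, self.pdf(x),
                                       {"construction": "linear_pool",
                                        "weights": self.weights.tolist()})

    def _finite_support(self) -> tuple[float, float]:
        lo, hi = self.support
        if np.isfinite(lo) and np.isfinite(hi):
            pad = 1e-9 * (hi - lo)
            return lo + pad, hi - pad
        # unbounded support: cover every component's central 99.9999%
        los, his = [], []
        for _, dens in self.components:
            los.append(dens.ppf(1e-7))
            his.append(dens.ppf(1 - 1e-7))
        return min(los), max(his)


def _component_support(density) -> tuple[float, float]:
    if isinstance(density, (BetaPrior, DensityGrid)):
        return (0.0, 1.0)
    if isinstance(density, NormalPrior):
        return (-np.inf, np.inf)
    if hasattr(density, "support_interval"):
        return tuple(density.support_interval)
    raise TypeError(f"cannot determine the support of {type(density).__name__}")


def linear_pool(densities, weights="equal") -> PooledDensity:
    """Equal- or fixed-weight linear opinion pool of expert densities.

    All densities must share a support; weights are renormalised to sum to one.
    """
    densities = list(densities)
    if not densities:
        raise ValueError("cannot pool an empty list of densities")
    supports = {_component_support(d) for d in densities}
    if len(supports) > 1:
        raise ValueError(f"densities do not share a support: {sorted(supports)}")
    if isinstance(weights, str):
        if weights != "equal":
            raise ValueError(f"unknown weight rule {weights!r}")
        w = np.full(len(densities), 1.0 / len(densities))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(densities),):
            raise ValueError(f"need one weight per density, got {w.shape}")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if w.sum() == 0:
            raise ValueError("weights must not all be zero")
        w = w / w.sum()
    return PooledDensity(tuple(zip(w.tolist(), densities)), supports.pop())


# ---------------------------------------------------------------------------
# model / results

class ExpertElicitation:
    """Elicitation model: expert quantile judgements for a two-arm trial prior.

    Built from a list of :class:`ExpertJudgement` or a long-format DataFrame
    with columns ``expert_id, quantity, prob, value``.  ``fit()`` fits each
    expert's judgements to the quantity's parametric family and pools the
    fitted densities per quantity with the given weights.
    """

    def __init__(self, judgements: list[ExpertJudgement]):
        judgements = list(judgements)
        if not judgements:
            raise ValueError("no judgements supplied")
        self.judgements = judgements

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ExpertElicitation":
        required = {"expert_id", "quantity", "prob", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"judgement table is missing columns {sorted(missing)}")
        judgements = []
        for (expert, quantity), grp in frame.groupby(
                ["expert_id", "quantity"], sort=True):
            grp = grp.sort_values("prob")
            try:
                judgements.append(ExpertJudgement(
                    str(expert), str(quantity),
                    tuple(grp["prob"]), tuple(grp["value"])))
            except InvalidJudgementError as err:
                rows = ", ".join(str(i) for i in grp.index.tolist())
                raise InvalidJudgementError(
                    f"rows [{rows}] (expert {expert!r}, {quantity}): {err}") from err
        return cls(judgements)

    def fit(self, weights="equal") -> "ElicitationResults":
        fitted: dict[tuple[str, str], BetaPrior | NormalPrior] = {}
        residuals: dict[tuple[str, str], float] = {}
        for j in self.judgements:
            prior = fit_judgement(j)
            fitted[(j.expert_id, j.quantity)] = prior
            fitted_q = (prior.ppf(np.asarray(j.probs))
                        if hasattr(prior, "ppf") else np.asarray(j.values))
            residuals[(j.expert_id, j.quantity)] = float(
                np.sqrt(np.sum((fitted_q - np.asarray(j.values)) ** 2)))
        pooled = {}
        for quantity in QUANTITIES:
            members = [p for (e, q), p in sorted(fitted.items()) if q == quantity]
            if members:
                pooled[quantity] = linear_pool(members, weights)
        return ElicitationResults(self, fitted, residuals, pooled)


@dataclass
class ElicitationResults:
    """Fitted per-expert priors, fit residuals and pooled densities."""

    model: ExpertElicitation
    expert_priors: dict
    residuals: dict
    pooled: dict = field(default_factory=dict)

    def prior(self, expert_id: str, quantity: str):
        return self.expert_priors[(expert_id, quantity)]

    def summary(self) -> pd.DataFrame:
        """One row per fitted (expert, quantity): family, parameters, residual."""
        rows = []
        for (expert, quantity), prior in sorted(self.expert_priors.items()):
            if isinstance(prior, BetaPrior):
                rows.append({"expert_id": expert, "quantity": quantity,
                             "family": "beta", "param1": prior.alpha,
                             "param2": prior.beta, "mean": prior.mean,
                             "ess": prior.ess,
                             "residual": self.residuals[(expert, quantity)]})
            else:
                rows.append({"expert_id": expert, "quantity": quantity,
                             "family": "normal", "param1": prior.mu,
                             "param2": prior.sigma, "mean": prior.mu,
                             "ess": np.nan,
                             "residual": self.residuals[(expert, quantity)]})
        return pd.DataFrame(rows)

    def pooled_mean(self, quantity: str) -> float:
        return self.pooled[quantity].mean()

    def plot(self, quantity: str = "control_response_rate", ax=None):
        """Overlay the individual fitted densities and the pooled mixture."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pool = self.pooled[quantity]
        lo, hi = pool._finite_support()
        x = np.linspace(lo, hi, 512)
        for (expert, q), prior in sorted(self.expert_priors.items()):
            if q == quantity:
                ax.plot(x, prior.pdf(x), lw=0.8, alpha=0.6, label=expert)
        ax.plot(x, pool.pdf(x), "k-", lw=2, label="linear pool")
        ax.set_xlabel(quantity.replace("_", " "))
        ax.set_ylabel("density")
        ax.legend(fontsize="x-small")
        return ax
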