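"""Analysis report: per-arm prior summaries, combined information, provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

from .priors import (BetaPrior, DensityGrid, beta_approximation,
                     effective_sample_size, moments)
from .trial import CONTROL_ARM, EXPERIMENTAL_ARM, TrialData, TrialDesign

__all__ = ["AnalysisReport", "ConfigError", "build_report"]


class ConfigError(ValueError):
    """Inconsistent configuration (e.g. endpoint labels that disagree)."""


@dataclass
class AnalysisReport:
    """Per-arm prior summaries with combined prior information and provenance."""

    arms: dict                      # arm -> summary dict
    combined_ess: float
    endpoint: str
    design: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"arms": self.arms, "combined_ess": self.combined_ess,
                "endpoint": self.endpoint, "design": self.design,
                "provenance": self.provenance}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_markdown(self) -> str:
        lines = [f"# Prior analysis report ({self.endpoint} endpoint)", "",
                 "| arm | family | parameters | mean | 95% interval | ESS |",
                 "|---|---|---|---|---|---|"]
        for arm, s in self.arms.items():
            pars = ", ".join(f"{k}={v:.4g}" for k, v in s["parameters"].items())
            lines.append(
                f"| {arm} | {s['family']} | {pars} | {s['mean']:.3f} | "
                f"({s['interval'][1]:.3f}, {s['interval'][2]:.3f}) | "
                f"{s['ess']:.1f} |")
        lines += ["", f"Combined prior ESS: **{self.combined_ess:.1f}** "
                      f"(per-arm planned n = {self.design.get('arm_n')})"]
        return "\n".join(lines)

    def summary(self) -> pd.DataFrame:
        rows = [{"arm": arm, **{k: v for k, v in s.items() if k != "interval"},
                 "lower": s["interval"][1], "upper": s["interval"][2]}
                for arm, s in self.arms.items()]
        return pd.DataFrame(rows)


def _summarise_prior(prior) -> dict:
    if isinstance(prior, DensityGrid):
        approx = beta_approximation(prior)
        m, _ = moments(prior)
        lo, hi = prior.interval(0.95)
        return {"family": "grid",
                "parameters": {"alpha_approx": approx.alpha,
                               "beta_approx": approx.beta},
                "mean": m, "interval": (0.95, lo, hi),
                "ess": effective_sample_size(approx)}
    if isinstance(prior, BetaPrior):
        lo, hi = prior.interval(0.95)
        return {"family": "beta",
                "parameters": {"alpha": prior.alpha, "beta": prior.beta},
                "mean": prior.mean, "interval": (0.95, lo, hi),
                "ess": effective_sample_size(prior)}
    raise TypeError(f"cannot summarise prior of type {type(prior).__name__}")


def build_report(control_prior, experimental_prior, design: TrialDesign,
                 data: TrialData | None = None, endpoint_label: str | None = None,
                 seed: int | None = None,
                 timestamp: bool = True) -> AnalysisReport:
    """Assemble the per-arm prior summaries into a deterministic report.

    ``endpoint_label`` (when the prior files carry one) must agree with the
    design's endpoint; a mismatch is a configuration error.  The report is
    byte-identical across runs with the same inputs, excluding the timestamp.
    """
    if endpoint_label is not None and endpoint_label != design.endpoint:
        raise ConfigError(
            f"priors are labelled for the {endpoint_label!r} endpoint but the "
            f"design specifies {design.endpoint!r}")
    arms = {CONTROL_ARM: _summarise_prior(control_prior),
            EXPERIMENTAL_ARM: _summarise_prior(experimental_prior)}
    combined = sum(s["ess"] for s in arms.values())
    provenance = {"package": "priorelicit", "seed": seed,
                  "operations": ["build_report", "effective_sample_size"]}
    if data is not None:
        provenance["data"] = {"control": list(data.control),
                              "experimental": list(data.experimental)}
    if timestamp:
        provenance["timestamp"] = datetime.now(timezone.utc).isoformat()
    return AnalysisReport(
        arms=arms, combined_ess=float(combined), endpoint=design.endpoint,
        design={"runin_n": design.runin_n,
                "runin_threshold": design.runin_threshold,
                "arm_n": design.arm_n,
                "superiority_cutoff": design.superiority_cutoff},
        provenance=provenance)


def plot_priors(control_prior, experimental_prior, ax=None):
    """Overlay the two arms' prior densities: control solid black, experimental
    dashed red."""
    import numpy as np
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(1e-4, 1 - 1e-4, 512)

    def dens(prior):
        if isinstance(prior, DensityGrid):
            return np.interp(x, prior.support, prior.density, left=0, right=0)
        return prior.pdf(x)

    ax.plot(x, dens(control_prior), "k-", label="control (ADA)")
    ax.plot(x, dens(experimental_prior), "r--", label="experimental (SEC)")
    ax.set_xlabel("response rate")
    ax.set_ylabel("prior density")
    ax.legend()
    return ax
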