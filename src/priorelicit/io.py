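"""Readers and writers for judgement tables, prior files, trial data and configs.

File formats are deliberately plain: long-format CSV (or an equivalent JSON
array) for expert judgements, JSON for priors (with construction provenance),
CSV for patient-level or aggregate trial data, YAML for design configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .elicitation import ExpertElicitation, ExpertJudgement
from .priors import BetaPrior, DensityGrid, NormalPrior
from .trial import CONTROL_ARM, EXPERIMENTAL_ARM, TrialData, TrialDesign

__all__ = [
    "read_judgements", "write_judgements",
    "prior_to_dict", "prior_from_dict", "write_priors", "read_priors",
    "read_trial_data", "read_design",
]


def read_judgements(path) -> list[ExpertJudgement]:
    """Read expert judgements from long-format CSV or a JSON array.

    CSV columns: ``expert_id, quantity, prob, value``.  JSON: a list of objects
    with ``expert_id``, ``quantity``, ``probs``, ``values``.  Invariant
    violations are reported with the offending rows.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [ExpertJudgement(r["expert_id"], r["quantity"],
                                tuple(r["probs"]), tuple(r["values"]))
                for r in records]
    frame = pd.read_csv(path)
    return ExpertElicitation.from_dataframe(frame).judgements


def write_judgements(judgements: list[ExpertJudgement], path) -> None:
    rows = [{"expert_id": j.expert_id, "quantity": j.quantity,
             "prob": p, "value": v}
            for j in judgements for p, v in zip(j.probs, j.values)]
    pd.DataFrame(rows).to_csv(path, index=False)


def prior_to_dict(prior, quantity: str = "", provenance: dict | None = None) -> dict:
    """JSON-serialisable representation of a beta, normal or grid prior."""
    out: dict = {"quantity": quantity}
    if isinstance(prior, BetaPrior):
        out.update(family="beta",
                   parameters={"alpha": prior.alpha, "beta": prior.beta})
    elif isinstance(prior, NormalPrior):
        out.update(family="normal",
                   parameters={"mu": prior.mu, "sigma": prior.sigma})
    elif isinstance(prior, DensityGrid):
        out.update(family="grid",
                   support=prior.support.tolist(),
                   density=prior.density.tolist(),
                   metadata={k: v for k, v in prior.metadata.items()
                             if _jsonable(v)})
    else:
        raise TypeError(f"cannot serialise prior of type {type(prior).__name__}")
    if provenance:
        out["provenance"] = provenance
    return out


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def prior_from_dict(d: dict):
    family = d.get("family")
    if family == "beta":
        return BetaPrior(**d["parameters"])
    if family == "normal":
        return NormalPrior(**d["parameters"])
    if family == "grid":
        return DensityGrid(np.asarray(d["support"]), np.asarray(d["density"]),
                           dict(d.get("metadata", {})))
    raise ValueError(f"unknown prior family {family!r}")


def write_priors(priors: dict, path, provenance: dict | None = None) -> None:
    """Write a mapping of name -> prior as a JSON document."""
    doc = {name: prior_to_dict(p, quantity=name) for name, p in priors.items()}
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2))


def read_priors(path) -> dict:
    doc = json.loads(Path(path).read_text())
    return {name: prior_from_dict(d) for name, d in doc.items()
            if name != "provenance"}


def read_trial_data(path, endpoint: str = "original") -> TrialData:
    """Read trial outcomes: patient-level grades or aggregate responder counts.

    Patient-level CSV columns: ``patient_id, arm, baseline_grade, week12_grade``
    (arms ``ADA``/``SEC``); aggregate CSV columns: ``arm, responders, n``.
    """
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if {"baseline_grade", "week12_grade"} <= cols:
        return TrialData.from_patients(frame, endpoint)
    if {"arm", "responders", "n"} <= cols:
        counts = {str(row["arm"]): (int(row["responders"]), int(row["n"]))
                  for _, row in frame.iterrows()}
        for arm in (CONTROL_ARM, EXPERIMENTAL_ARM):
            if arm not in counts:
                raise ValueError(f"arm {arm!r} missing from {path}")
        return TrialData(counts[CONTROL_ARM], counts[EXPERIMENTAL_ARM])
    raise ValueError(
        f"{path}: expected patient-level columns (arm, baseline_grade, "
        f"week12_grade) or aggregate columns (arm, responders, n); got "
        f"{sorted(cols)}")


def read_design(path) -> TrialDesign:
    """Read a design config (YAML or JSON) into a TrialDesign."""
    raw = Path(path).read_text()
    cfg = yaml.safe_load(raw) or {}
    known = {k: cfg[k] for k in ("runin_n", "runin_threshold", "arm_n",
                                 "endpoint", "superiority_cutoff", "grid_size")
             if k in cfg}
    return TrialDesign(**known)
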