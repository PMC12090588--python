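"""SUN anterior-chamber cell grades and the week-12 response endpoint.

Grades form the ordinal scale 0 < 0.5+ < 1+ < 2+ < 3+ < 4+; a "step" is one
position on that scale.  The original endpoint counts a patient as a responder
when the grade drops by at least two steps or reaches 0; the revised endpoint
additionally counts any decrease reaching grade 0.5.
"""

from __future__ import annotations

__all__ = ["GRADES", "ELIGIBLE_BASELINES", "grade_rank", "classify_response",
           "IneligiblePatientError"]

GRADES: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)
_RANK = {g: i for i, g in enumerate(GRADES)}

#: baselines with active inflammation (grade > 0), required for trial entry
ELIGIBLE_BASELINES: tuple[float, ...] = GRADES[1:]

ENDPOINTS = ("original", "revised")


class IneligiblePatientError(ValueError):
    """Baseline grade 0: no active inflammation, patient not eligible."""


def grade_rank(grade: float) -> int:
    """Ordinal rank of a SUN grade (0 -> 0, 0.5 -> 1, ..., 4 -> 5)."""
    try:
        return _RANK[float(grade)]
    except KeyError:
        raise ValueError(
            f"invalid SUN anterior-chamber cell grade {grade!r}; "
            f"must be one of {GRADES}") from None


def classify_response(baseline: float, week12: float,
                      endpoint: str = "original") -> bool:
    """Classify one patient's baseline -> week-12 grade change as response.

    Original endpoint: a decrease of at least two steps, or a decrease to
    grade 0.  Revised endpoint: additionally, any decrease reaching grade 0.5.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of "
                         f"{ENDPOINTS}")
    rb, rw = grade_rank(baseline), grade_rank(week12)
    if rb == 0:
        raise IneligiblePatientError(
            "baseline grade 0 means no active inflammation; patient ineligible")
    responder = (rb - rw >= 2) or (rw == 0)
    if endpoint == "revised":
        responder = responder or (rw <= _RANK[0.5] and rw < rb)
    return responder
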