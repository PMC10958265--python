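"""Outcome and covariate construction from questionnaire-style indicators.

The outcome state distinguishes unmet from met healthcare needs: a
respondent has unmet needs if they were ill in the past month without any
outpatient contact, or had a recommended hospitalisation in the past year
that did not happen.  Depression is screened with the CES-D-10 (range
0-30, cut-off >= 10) and counts as one mental condition when grouping
chronic conditions into the three-level multimorbidity variable
(none / physical-only P / mixed physical-mental PM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .panel import STATE_MET, STATE_UNMET

MultimorbidityCategory = Literal["none", "P", "PM"]

#: default chronic-condition list (name, is_mental); the mental subset is
#: configurable because classification conventions differ across surveys
DEFAULT_CONDITIONS: tuple[tuple[str, bool], ...] = (
    ("hypertension", False),
    ("dyslipidemia", False),
    ("diabetes", False),
    ("cancer", False),
    ("chronic_lung_disease", False),
    ("liver_disease", False),
    ("heart_disease", False),
    ("stroke", False),
    ("kidney_disease", False),
    ("digestive_disease", False),
    ("arthritis", False),
    ("asthma", False),
    ("psychiatric_problems", True),
    ("memory_related_disease", True),
)


@dataclass(frozen=True)
class NeedsIndicators:
    ill_last_month: bool
    outpatient_used: bool
    inpatient_recommended: bool
    hospitalised: bool


@dataclass(frozen=True)
class CesdResponse:
    """Ten CES-D item scores, each in 0..3."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError("CES-D-10 requires exactly 10 items")
        if any((not 0 <= i <= 3) for i in self.items):
            raise ValueError("each CES-D item must be in 0..3")


@dataclass(frozen=True)
class ConditionChecklist:
    physical_conditions: frozenset[str] = frozenset()
    depressed: bool = False
    mental_conditions: frozenset[str] = frozenset()
    condition_list: tuple[tuple[str, bool], ...] = field(default=DEFAULT_CONDITIONS)

    def __post_init__(self) -> None:
        phys = {n for n, mental in self.condition_list if not mental}
        ment = {n for n, mental in self.condition_list if mental}
        if not set(self.physical_conditions) <= phys:
            raise ValueError(f"unknown physical condition(s): {set(self.physical_conditions) - phys}")
        if not set(self.mental_conditions) <= ment:
            raise ValueError(f"unknown mental condition(s): {set(self.mental_conditions) - ment}")


def derive_needs_state(ind: NeedsIndicators) -> int:
    """Return 1 (unmet) or 2 (met healthcare needs).

    Unmet if either trigger fires: illness without outpatient use, or a
    recommended hospitalisation not taken up.  Respondents with no
    perceived need are coded met (state 2).
    """
    unmet_outpatient = ind.ill_last_month and not ind.outpatient_used
    unmet_inpatient = ind.inpatient_recommended and not ind.hospitalised
    return STATE_UNMET if (unmet_outpatient or unmet_inpatient) else STATE_MET


def score_cesd10(r: CesdResponse | Sequence[int]) -> tuple[int, bool]:
    """Total CES-D-10 score and the depression flag (total >= 10)."""
    if not isinstance(r, CesdResponse):
        r = CesdResponse(tuple(int(i) for i in r))
    total = sum(r.items)
    return total, total >= 10


def classify_multimorbidity(
    c: ConditionChecklist, *, rule: Literal["mixed", "strict"] = "mixed"
) -> MultimorbidityCategory:
    """Group conditions into none / P / PM multimorbidity.

    Depression (CES-D >= 10) counts as one mental condition alongside the
    checklist's mental illnesses.  Two decision rules are offered for the
    mixed category:

    ``mixed`` (default)
        PM if there are >= 2 conditions in total with at least one physical
        and one mental; otherwise P if >= 2 physical; otherwise none.
    ``strict``
        PM requires >= 2 physical AND >= 2 mental conditions.
    """
    n_phys = len(c.physical_conditions)
    n_ment = len(c.mental_conditions) + (1 if c.depressed else 0)
    if rule == "mixed":
        if n_phys + n_ment >= 2 and n_phys >= 1 and n_ment >= 1:
            return "PM"
    elif rule == "strict":
        if n_phys >= 2 and n_ment >= 2:
            return "PM"
    else:
        raise ValueError(f"unknown multimorbidity rule {rule!r}")
    if n_phys >= 2:
        return "P"
    return "none"
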