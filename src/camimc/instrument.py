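"""CAM-IMC scoring rules.

The Confusion Assessment Method for the Intermediate Care Unit (CAM-IMC)
screens non-intubated patients for postoperative delirium.  It combines
three CAM-ICU features — acute change or fluctuating course of mental
status, altered level of consciousness (RASS != 0), and inattention on a
ten-letter squeeze task — with a five-dimension verbal disorientation
test (age, date of birth, place, year, situational awareness).

Points are additive:

=====================  ======  ==========================================
feature                points  rule
=====================  ======  ==========================================
fluctuation            0 or 1  1 if an acute change / fluctuating course
                               of mental status is present
consciousness          0 or 1  1 if RASS != 0
inattention            0..3    one point per error, capped at three
disorientation         0..5    one point per dimension answered in error
=====================  ======  ==========================================

The total ranges 0–10 and the test is positive at a configurable
cut-off (default 3).  Because inattention contributes up to three
points and disorientation up to five, either of those features alone
can trigger a positive result, whereas fluctuation plus altered
consciousness together (2 points) cannot.

Patients at RASS -4 or -5 are unarousable and cannot be assessed; such
records are flagged ``assessable=False`` and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

__all__ = [
    "DISORIENTATION_DIMENSIONS",
    "DEFAULT_CUTOFF",
    "INATTENTION_ITEM_CUTOFF",
    "DISORIENTATION_ITEM_CUTOFF",
    "MissingPolicy",
    "UnassessableError",
    "BaselineAssessment",
    "FeatureResponses",
    "CamImcScore",
    "ReferenceDiagnosis",
    "ItemFlags",
    "SubgroupFlags",
    "score_inattention",
    "score_disorientation",
    "score_consciousness",
    "cam_imc",
    "item_flags",
    "subgroup_flags",
]

#: The five verbal disorientation dimensions, in canonical column order.
DISORIENTATION_DIMENSIONS = (
    "age",
    "date_of_birth",
    "place",
    "year",
    "situational_awareness",
)

#: Default positivity cut-off on the 0-10 total.
DEFAULT_CUTOFF = 3

#: Item-level dichotomisation: inattention positive at >= 3 errors.
INATTENTION_ITEM_CUTOFF = 3
#: Item-level dichotomisation: disorientation positive at >= 2 dimension errors.
DISORIENTATION_ITEM_CUTOFF = 2

_MAX_INATTENTION_POINTS = 3
_MAX_LETTERS = 10
_RASS_MIN, _RASS_MAX = -5, 4
#: RASS at or below this level means the patient is unarousable.
_UNAROUSABLE_RASS = -4

MissingPolicy = Literal["strict", "lenient"]


class UnassessableError(ValueError):
    """Raised when a feature response cannot be scored (missing or unarousable)."""


def _check_rass(rass: int) -> None:
    if not (_RASS_MIN <= rass <= _RASS_MAX):
        raise ValueError(f"RASS must be in [{_RASS_MIN}, {_RASS_MAX}], got {rass}")


@dataclass(frozen=True)
class BaselineAssessment:
    """Preoperative baseline for one patient.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    age : int
        Age in years; the cohort inclusion criterion is age >= 50.
    sex : {"male", "female"}
    minicog : int, optional
        Mini-Cog result, 0-5; a result below 3 suggests pre-existing
        cognitive impairment.
    baseline_orientation : int, optional
        Preoperative orientation, one point per correct category
        (age, birthday, situation, location, time), 0-5.
    baseline_rass : int, optional
        Preoperative RASS, -5 (unarousable) to +4 (combative).
    """

    patient_id: str
    age: int
    sex: str
    minicog: Optional[int] = None
    baseline_orientation: Optional[int] = None
    baseline_rass: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.minicog is not None and not (0 <= self.minicog <= 5):
            raise ValueError(f"minicog must be in [0, 5], got {self.minicog}")
        if self.baseline_orientation is not None and not (
            0 <= self.baseline_orientation <= 5
        ):
            raise ValueError(
                f"baseline_orientation must be in [0, 5], got {self.baseline_orientation}"
            )
        if self.baseline_rass is not None:
            _check_rass(self.baseline_rass)


@dataclass(frozen=True)
class FeatureResponses:
    """One rater's raw CAM-IMC item responses for one patient-day.

    Missing responses are encoded as ``None``; disorientation dimensions
    use ``True`` for an error, ``False`` for a correct answer and
    ``None`` for missing.
    """

    fluctuation_present: Optional[bool]
    rass: Optional[int]
    inattention_errors: Optional[int]
    disorientation: Mapping[str, Optional[bool]]

    def __post_init__(self) -> None:
        if self.rass is not None:
            _check_rass(self.rass)
        if self.inattention_errors is not None:
            if not (0 <= self.inattention_errors <= _MAX_LETTERS):
                raise ValueError(
                    "inattention_errors must be in "
                    f"[0, {_MAX_LETTERS}], got {self.inattention_errors}"
                )
        if set(self.disorientation) != set(DISORIENTATION_DIMENSIONS):
            raise ValueError(
                "disorientation must supply exactly the dimensions "
                f"{DISORIENTATION_DIMENSIONS}, got {tuple(self.disorientation)}"
            )


@dataclass(frozen=True)
class ReferenceDiagnosis:
    """Reference-standard delirium diagnosis (expert DSM-5 based rating)."""

    delirium: bool
    basis: str = "dsm5"


@dataclass(frozen=True)
class CamImcScore:
    """Scored CAM-IMC assessment.

    ``total = pts_fluctuation + pts_consciousness + pts_inattention +
    pts_disorientation`` and ``positive <=> total >= cutoff`` whenever
    the record is assessable.  When it is not, the point fields are
    ``None`` and ``reasons`` explains why.
    """

    pts_fluctuation: Optional[int]
    pts_consciousness: Optional[int]
    pts_inattention: Optional[int]
    pts_disorientation: Optional[int]
    total: Optional[int]
    cutoff: int
    positive: Optional[bool]
    assessable: bool
    complete: bool = True
    reasons: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class ItemFlags:
    """Item-level dichotomisations (``None`` where the response is missing)."""

    fluctuation: Optional[bool]
    consciousness: Optional[bool]
    inattention: Optional[bool]
    disorientation: Optional[bool]


@dataclass(frozen=True)
class SubgroupFlags:
    """Subgroup membership derived from the preoperative baseline."""

    elderly: bool
    cognitive_impairment: Optional[bool]


def score_inattention(errors: int) -> int:
    """Points for the inattention (letter-squeeze) task.

    The patient squeezes the examiner's hand at each letter "A" of a
    ten-letter word; each mistake scores one point, capped at three.
    """
    if errors is None:
        raise UnassessableError("inattention response missing")
    if errors < 0:
        raise ValueError(f"error count must be non-negative, got {errors}")
    return min(int(errors), _MAX_INATTENTION_POINTS)


def score_disorientation(
    dim_results: Mapping[str, Optional[bool]],
    policy: MissingPolicy = "strict",
) -> int:
    """Points for the five-dimension disorientation test.

    Each dimension answered in error scores one point (maximum five).
    Under the strict policy a missing dimension makes the feature
    unassessable; under the lenient policy errors are counted among the
    answered dimensions.
    """
    if set(dim_results) != set(DISORIENTATION_DIMENSIONS):
        raise ValueError(
            f"expected dimensions {DISORIENTATION_DIMENSIONS}, got {tuple(dim_results)}"
        )
    missing = [d for d, r in dim_results.items() if r is None]
    if missing and policy == "strict":
        raise UnassessableError(f"disorientation dimensions missing: {missing}")
    return sum(1 for r in dim_results.values() if r is True)


def score_consciousness(rass: int) -> int:
    """Points for altered level of consciousness: 1 if RASS != 0.

    RASS -4 and -5 mean the patient does not respond to voice; the
    assessment cannot be performed and the record is unassessable.
    """
    if rass is None:
        raise UnassessableError("RASS missing")
    _check_rass(rass)
    if rass <= _UNAROUSABLE_RASS:
        raise UnassessableError(f"patient unarousable at RASS {rass}")
    return 0 if rass == 0 else 1


def cam_imc(
    responses: FeatureResponses,
    cutoff: int = DEFAULT_CUTOFF,
    policy: MissingPolicy = "strict",
) -> CamImcScore:
    """Score one CAM-IMC assessment.

    Parameters
    ----------
    responses : FeatureResponses
        Raw item responses.
    cutoff : int
        Positivity cut-off on the 0-10 total (default 3).
    policy : {"strict", "lenient"}
        Missing-data policy.  ``strict`` (default) marks any record with
        a missing feature response unassessable; ``lenient`` scores the
        answered items (missing items contribute zero points) and marks
        the record ``complete=False``.  An unarousable patient
        (RASS <= -4) is unassessable under either policy.

    Returns
    -------
    CamImcScore
        With ``assessable=False`` and ``None`` point fields when the
        record cannot be scored under the chosen policy.
    """
    if not (0 <= cutoff <= 10):
        raise ValueError(f"cutoff must be in [0, 10], got {cutoff}")
    reasons: list[str] = []
    complete = True

    # Unarousable patients cannot be assessed regardless of policy.
    if responses.rass is not None:
        _check_rass(responses.rass)
        if responses.rass <= _UNAROUSABLE_RASS:
            return CamImcScore(
                None, None, None, None, None, cutoff, None,
                assessable=False, complete=False,
                reasons=(f"patient unarousable at RASS {responses.rass}",),
            )

    def _component(value, fn, label):
        nonlocal complete
        if value is None:
            reasons.append(f"{label} response missing")
            complete = False
            return None
        return fn(value)

    pts_f = _component(
        responses.fluctuation_present, lambda v: 1 if v else 0, "fluctuation"
    )
    pts_c = _component(responses.rass, score_consciousness, "RASS")
    pts_i = _component(responses.inattention_errors, score_inattention, "inattention")

    dis_missing = any(r is None for r in responses.disorientation.values())
    if dis_missing:
        complete = False
        reasons.append("disorientation dimension(s) missing")
    if dis_missing and policy == "strict":
        pts_d = None
    else:
        pts_d = score_disorientation(responses.disorientation, policy="lenient")

    if policy == "strict" and not complete:
        return CamImcScore(
            None, None, None, None, None, cutoff, None,
            assessable=False, complete=False, reasons=tuple(reasons),
        )

    total = sum(p or 0 for p in (pts_f, pts_c, pts_i, pts_d))
    return CamImcScore(
        pts_fluctuation=pts_f if pts_f is not None else 0,
        pts_consciousness=pts_c if pts_c is not None else 0,
        pts_inattention=pts_i if pts_i is not None else 0,
        pts_disorientation=pts_d,
        total=total,
        cutoff=cutoff,
        positive=total >= cutoff,
        assessable=True,
        complete=complete,
        reasons=tuple(reasons),
    )


def item_flags(responses: FeatureResponses) -> ItemFlags:
    """Dichotomise each CAM-IMC item for the item-level accuracy analysis.

    Cut-offs: inattention positive at three or more errors;
    disorientation positive at two or more dimension errors; RASS != 0
    and fluctuation are binary as assessed.  A missing response yields
    ``None`` for that item.
    """
    fluct = responses.fluctuation_present
    cons = None
    if responses.rass is not None and responses.rass > _UNAROUSABLE_RASS:
        cons = responses.rass != 0
    inatt = None
    if responses.inattention_errors is not None:
        inatt = responses.inattention_errors >= INATTENTION_ITEM_CUTOFF
    disor = None
    if all(r is not None for r in responses.disorientation.values()):
        n_err = sum(1 for r in responses.disorientation.values() if r)
        disor = n_err >= DISORIENTATION_ITEM_CUTOFF
    return ItemFlags(
        fluctuation=fluct, consciousness=cons, inattention=inatt, disorientation=disor
    )


def subgroup_flags(baseline: BaselineAssessment) -> SubgroupFlags:
    """Subgroup membership: elderly (age >= 65) and pre-existing
    cognitive impairment (Mini-Cog < 3).

    A missing Mini-Cog leaves ``cognitive_impairment`` as ``None``; the
    record is then excluded from that subgroup only.
    """
    return SubgroupFlags(
        elderly=baseline.age >= 65,
        cognitive_impairment=(
            None if baseline.minicog is None else baseline.minicog < 3
        ),
    )
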