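"""Longitudinal covariates derived from per-wave items.

Collapses each woman's six-wave covariate items into the analysis
variables: relationship trajectory (in terms of ever being separated or
divorced), "highly stressed for at least half of completed surveys"
indicators for partner and income stress, the answered-survey-count
category, and the design weight that undoes the two-fold oversampling of
rural and remote women.

A record missing any regression covariate is flagged incomplete rather
than dropped here; the regression module performs (and reports) the
complete-case restriction.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import ConsistencyClass, classify
from .cohort import SEP_DIV, Cohort, WomanRecord

__all__ = [
    "RelationshipTrajectory",
    "NSurveysCat",
    "DEFAULT_WEIGHT_SCHEME",
    "derive_trajectory",
    "derive_stress_half",
    "assign_weight",
    "build_profiles",
]


class RelationshipTrajectory(Enum):
    NEVER_SEP_DIV = "never_sep_div"
    REMAINED_SEP_DIV = "remained_sep_div"
    BECAME_PARTNERED = "became_partnered"
    BECAME_SEP_DIV = "became_sep_div"


class NSurveysCat(Enum):
    SIX = "six"
    FIVE = "five"
    THREE_FOUR = "three_four"


#: rural and remote strata were sampled at twice the rate of major cities,
#: so their records carry half weight in descriptive percentages
DEFAULT_WEIGHT_SCHEME: Mapping[str, float] = {
    "major_city": 1.0,
    "inner_regional": 0.5,
    "outer_regional": 0.5,
    "remote_very_remote": 0.5,
}


def derive_trajectory(statuses: Sequence[Optional[str]]) -> Optional[RelationshipTrajectory]:
    """Trajectory of separated/divorced status over answered waves.

    Uses the first and last non-missing status plus an "ever separated or
    divorced" flag; multi-transition histories resolve by those endpoints.
    Returns ``None`` when every status is missing.
    """
    answered = [s for s in statuses if s is not None]
    if not answered:
        return None
    sep = [s in SEP_DIV for s in answered]
    if not any(sep):
        return RelationshipTrajectory.NEVER_SEP_DIV
    b, e = sep[0], sep[-1]
    if b and e:
        return RelationshipTrajectory.REMAINED_SEP_DIV
    if b:
        return RelationshipTrajectory.BECAME_PARTNERED
    return RelationshipTrajectory.BECAME_SEP_DIV


def derive_stress_half(indicator: Sequence[Optional[bool]]) -> Optional[bool]:
    """True iff highly stressed at >= half of the waves with a non-missing item."""
    answered = [v for v in indicator if v is not None]
    if not answered:
        return None
    return sum(answered) / len(answered) >= 0.5


def assign_weight(area: Optional[str], scheme: Optional[Mapping[str, float]] = None) -> Optional[float]:
    """Design weight for an area stratum (``None`` when area is missing)."""
    if area is None:
        return None
    scheme = DEFAULT_WEIGHT_SCHEME if scheme is None else scheme
    w = scheme[area]
    if not w > 0:
        raise ValueError(f"weight for {area!r} must be positive, got {w}")
    return w


def _n_surveys_cat(answered_count: int) -> NSurveysCat:
    if answered_count == 6:
        return NSurveysCat.SIX
    if answered_count == 5:
        return NSurveysCat.FIVE
    return NSurveysCat.THREE_FOUR


def _baseline_rel3(status: Optional[str]) -> Optional[str]:
    """Collapse wave-1 relationship status to the three printed groups."""
    if status is None:
        return None
    if status in ("married", "defacto"):
        return "married_defacto"
    if status in SEP_DIV:
        return "divorced_separated"
    return "widowed_single"


def build_profiles(
    cohort: Cohort,
    weight_scheme: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Analysis-ready table: one row per record, keyed by id.

    Columns: ``consistency_class``, the derived covariates, ``weight`` and a
    ``complete`` flag marking records with every regression covariate
    observed.  Weight defaults to 1.0 for records with missing area so that
    descriptive totals remain defined; such records are flagged incomplete.
    """
    rows = []
    for r in cohort:
        cls = classify(r.ipv)
        traj = derive_trajectory(r.relationship_status)
        pstress = derive_stress_half(r.partner_stress_high)
        istress = derive_stress_half(r.income_stress_high)
        weight = assign_weight(r.area, weight_scheme)
        complete = all(
            v is not None for v in (r.area, r.qualification, traj, pstress, istress)
        )
        rows.append(
            {
                "id": r.id,
                "consistency_class": cls.value,
                "area": r.area,
                "qualification": r.qualification,
                "trajectory": traj.value if traj else None,
                "partner_stress_half": pstress,
                "income_stress_half": istress,
                "partner_stress_w1": r.partner_stress_high[0],
                "income_stress_w1": r.income_stress_high[0],
                "baseline_rel": _baseline_rel3(r.relationship_status[0]),
                "answered_count": r.answered_count,
                "n_surveys_cat": _n_surveys_cat(r.answered_count).value,
                "weight": 1.0 if weight is None else weight,
                "complete": complete,
            }
        )
    return pd.DataFrame(rows).set_index("id")
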