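"""Derived per-decision quantities.

Every quantity is a simple function of one decision record and, where needed,
the cohort constants:

* adjustment level      ``aia - un``   (did AI assistance move the decision?)
* dissimilarity         ``ai - un``    (how far was AI from the prior view?)
* agreement             ``-|aia - ai|`` (peaks at 0 when the assisted decision
  equals the recommendation)
* closeness to SOC      ``-|d - SOC|``  for d in {un, aia}
* trust score           0-5 rubric over the four trust questions (1+1+2+1)
* influence class       the four-cell truth table crossing "did un equal ai?"
  with "did the evaluator adjust?"
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    DOSE_TOL,
    CohortConfig,
    DecisionRecord,
    RecommendationView,
    OutcomeReasonable,
    OutcomeUncertainty,
    RecommendationUncertainty,
    TrustAnswers,
    ValidationError,
)


class InfluenceClass(str, enum.Enum):
    """AI-influence truth table over (un = ai?) x (un = aia?).

    NOT_SURE: the evaluator already matched the AI and did not move — influence
    indeterminable. ADJUSTED_VIA_RTOE: moved away although un = ai, i.e. the
    adjustment bypassed the recommendation and must rest on the outcome
    estimate (RTOE). NO_INFLUENCE: disagreed with AI and stayed put.
    ADJUSTED_WITH_AI: disagreed and moved.
    """

    NO_INFLUENCE = "NO_INFLUENCE"
    NOT_SURE = "NOT_SURE"
    ADJUSTED_WITH_AI = "ADJUSTED_WITH_AI"
    ADJUSTED_VIA_RTOE = "ADJUSTED_VIA_RTOE"


def doses_equal(a: float, b: float, tol: float = DOSE_TOL) -> bool:
    """Dose equality at the configured resolution (|a - b| <= tol)."""
    return abs(a - b) <= tol


def adjustment_level(rec: DecisionRecord) -> float:
    """Decision adjustment level, ``aia - un`` (Gy/fx)."""
    return rec.aia - rec.un


def adjustment_flag(rec: DecisionRecord, tol: float = DOSE_TOL) -> bool:
    return not doses_equal(rec.aia, rec.un, tol)


def dissimilarity(rec: DecisionRecord) -> float:
    """Dissimilarity in decision-making with AI, ``ai - un`` (Gy/fx)."""
    return rec.ai - rec.un


def agreement(rec: DecisionRecord) -> float:
    """Agreement with AI, ``-|aia - ai|``; maximal (0) when aia = ai."""
    return -abs(rec.aia - rec.ai)


def closeness_to_soc(d: float, cohort: CohortConfig) -> float:
    """Closeness of a dose to the standard of care, ``-|d - SOC|``."""
    if not cohort.contains(d):
        raise ValidationError(
            f"dose {d} outside [{cohort.dose_min}, {cohort.dose_max}]"
        )
    return -abs(d - cohort.soc_dose)


def delta_conf(rec: DecisionRecord) -> int:
    """Change in confidence, ``aia_conf - un_conf`` (integer, -5..5)."""
    return rec.aia_conf - rec.un_conf


def trust_score(answers: TrustAnswers) -> int:
    """0-5 trust rubric: 2 points for agreeing with the recommended dose
    range, 1 point for each of the three reasonableness judgements; only the
    first option of each question carries points."""
    score = 0
    if answers.outcome_reasonable is OutcomeReasonable.REASONABLE:
        score += 1
    if answers.outcome_uncertainty is OutcomeUncertainty.REASONABLE:
        score += 1
    if answers.recommendation_view is RecommendationView.AGREE:
        score += 2
    if answers.recommendation_uncertainty is RecommendationUncertainty.REASONABLE:
        score += 1
    return score


def classify_influence(rec: DecisionRecord, tol: float = DOSE_TOL) -> InfluenceClass:
    similar = doses_equal(rec.un, rec.ai, tol)
    adjusted = not doses_equal(rec.un, rec.aia, tol)
    if similar and not adjusted:
        return InfluenceClass.NOT_SURE
    if similar and adjusted:
        return InfluenceClass.ADJUSTED_VIA_RTOE
    if not similar and not adjusted:
        return InfluenceClass.NO_INFLUENCE
    return InfluenceClass.ADJUSTED_WITH_AI


@dataclass(frozen=True)
class AdjustmentFrequency:
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def adjustment_frequency(
    records: Sequence[DecisionRecord], tol: float = DOSE_TOL
) -> AdjustmentFrequency:
    """Count of adjusted decisions (un != aia at the dose resolution)."""
    if not records:
        raise ValidationError("adjustment_frequency of an empty collection")
    count = sum(adjustment_flag(r, tol) for r in records)
    return AdjustmentFrequency(count=count, total=len(records))


DERIVED_COLUMNS = [
    "evaluator_id",
    "patient_id",
    "un",
    "aia",
    "ai",
    "un_conf",
    "aia_conf",
    "trust_level",
    "adjustment_flag",
    "adjustment_level",
    "dissimilarity",
    "agreement",
    "closeness_un",
    "closeness_aia",
    "delta_conf",
    "influence_class",
]


def derive_table(
    records: Iterable[DecisionRecord],
    cohort: CohortConfig,
    tol: float = DOSE_TOL,
) -> pd.DataFrame:
    """Tidy table: one row per record with all derived metrics appended."""
    rows = []
    for r in records:
        rows.append(
            {
                "evaluator_id": r.evaluator_id,
                "patient_id": r.patient_id,
                "un": r.un,
                "aia": r.aia,
                "ai": r.ai,
                "un_conf": r.un_conf,
                "aia_conf": r.aia_conf,
                "trust_level": r.trust_level,
                "adjustment_flag": adjustment_flag(r, tol),
                "adjustment_level": adjustment_level(r),
                "dissimilarity": dissimilarity(r),
                "agreement": agreement(r),
                "closeness_un": closeness_to_soc(r.un, cohort),
                "closeness_aia": closeness_to_soc(r.aia, cohort),
                "delta_conf": delta_conf(r),
                "influence_class": classify_influence(r, tol).value,
            }
        )
    return pd.DataFrame(rows, columns=DERIVED_COLUMNS)
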