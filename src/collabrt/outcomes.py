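"""TCP/NTCP outcome-space computations.

The outcome of a dose decision is read off a per-patient curve pair
(tcp(d), ntcp(d)) by linear interpolation. Adjusted decisions are classified
by whether both probabilities rose, both fell, or moved in opposite
directions, and scored with the toxicity-free local control schema
``TCP * (1 - NTCP)`` — 1 at the ideal corner (tcp, ntcp) = (1, 0), 0 whenever
ntcp = 1. The reward function adds threshold bonuses on top of that baseline
(+1 for the computational goal tcp > 0.5 & ntcp < 0.5, +2 instead for the
cohort's clinical goal), and EQD2 gives the total linear-quadratic equivalent
dose in 2 Gy fractions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .metrics import adjustment_flag
from .records import (
    DOSE_TOL,
    CohortConfig,
    DecisionRecord,
    OutcomeCurve,
    ValidationError,
)


class OutcomePoint(NamedTuple):
    tcp: float
    ntcp: float


def interpolate_outcome(curve: OutcomeCurve, dose: float) -> OutcomePoint:
    """Linear interpolation of (tcp, ntcp) at ``dose``; exact at grid points,
    no extrapolation outside the grid span."""
    if not (curve.doses[0] - 1e-9 <= dose <= curve.doses[-1] + 1e-9):
        raise ValidationError(
            f"dose {dose} outside curve span [{curve.doses[0]}, {curve.doses[-1]}] "
            f"for patient {curve.patient_id}"
        )
    return OutcomePoint(
        tcp=float(np.interp(dose, curve.doses, curve.tcp_mean)),
        ntcp=float(np.interp(dose, curve.doses, curve.ntcp_mean)),
    )


def score(p: OutcomePoint) -> float:
    """Toxicity-free local control score, tcp * (1 - ntcp) in [0, 1]."""
    return p.tcp * (1.0 - p.ntcp)


def reward(p: OutcomePoint, cohort: CohortConfig) -> float:
    """Thresholded reward: the score baseline plus +2 when the cohort's
    clinical goal is met (strict inequalities), else +1 for the computational
    goal tcp > 0.5 and ntcp < 0.5, else nothing."""
    r = score(p)
    if p.tcp > cohort.reward_tcp_high and p.ntcp < cohort.reward_ntcp_low:
        return r + 2.0
    if p.tcp > 0.5 and p.ntcp < 0.5:
        return r + 1.0
    return r


class OutcomeCategory(str, enum.Enum):
    BOTH_INCREASE = "BOTH_INCREASE"
    BOTH_DECREASE = "BOTH_DECREASE"
    MIXED = "MIXED"


@dataclass(frozen=True)
class OutcomeChange:
    evaluator_id: str
    patient_id: str
    tcp_un: float
    ntcp_un: float
    tcp_aia: float
    ntcp_aia: float
    category: OutcomeCategory
    score_un: float
    score_aia: float

    @property
    def score_diff(self) -> float:
        return self.score_aia - self.score_un


def _categorize(dtcp: float, dntcp: float) -> OutcomeCategory:
    if dtcp > 0 and dntcp > 0:
        return OutcomeCategory.BOTH_INCREASE
    if dtcp < 0 and dntcp < 0:
        return OutcomeCategory.BOTH_DECREASE
    return OutcomeCategory.MIXED


def classify_outcome_changes(
    records: Sequence[DecisionRecord],
    curves: Sequence[OutcomeCurve],
    tol: float = DOSE_TOL,
) -> tuple[list[OutcomeChange], dict[str, int]]:
    """Outcome change of every *adjusted* decision (un != aia).

    Unadjusted records are excluded — only adjustments can change the
    outcome. Returns the per-record changes and the category counts, which
    partition the adjusted set exactly.
    """
    by_patient = {c.patient_id: c for c in curves}
    changes: list[OutcomeChange] = []
    for rec in records:
        if not adjustment_flag(rec, tol):
            continue
        curve = by_patient.get(rec.patient_id)
        if curve is None:
            raise ValidationError(f"no outcome curve for patient {rec.patient_id}")
        p_un = interpolate_outcome(curve, rec.un)
        p_aia = interpolate_outcome(curve, rec.aia)
        changes.append(
            OutcomeChange(
                evaluator_id=rec.evaluator_id,
                patient_id=rec.patient_id,
                tcp_un=p_un.tcp,
                ntcp_un=p_un.ntcp,
                tcp_aia=p_aia.tcp,
                ntcp_aia=p_aia.ntcp,
                category=_categorize(p_aia.tcp - p_un.tcp, p_aia.ntcp - p_un.ntcp),
                score_un=score(p_un),
                score_aia=score(p_aia),
            )
        )
    counts = {cat.value: 0 for cat in OutcomeCategory}
    for ch in changes:
        counts[ch.category.value] += 1
    return changes, counts


@dataclass(frozen=True)
class ScoreDiffSummary:
    """Summary statistics of the pairwise score differences
    (aia score - un score), reported at four decimals."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    @property
    def skew_direction(self) -> str:
        if self.mean > self.median:
            return "right"
        if self.mean < self.median:
            return "left"
        return "none"


def score_diff_summary(changes: Sequence[OutcomeChange]) -> ScoreDiffSummary:
    """Mean, sample SD (n-1), median and quartiles (linear interpolation
    between order statistics) of score_diff."""
    if not changes:
        raise ValidationError("score_diff_summary of an empty collection")
    diffs = np.array([c.score_diff for c in changes], float)
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    q1, med, q3 = np.percentile(diffs, [25, 50, 75])
    return ScoreDiffSummary(
        n=diffs.size,
        mean=float(diffs.mean()),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def total_eqd2(dose_per_fx: float, n_fractions: int, alpha_beta: float = 10.0) -> float:
    """Total equivalent dose in 2 Gy fractions under the linear-quadratic
    model: n * d * (d + alpha/beta) / (2 + alpha/beta). A 2 Gy/fx schedule is
    its own EQD2; alpha/beta defaults to the 10 Gy tumor convention."""
    if alpha_beta <= 0:
        raise ValidationError("alpha_beta must be positive")
    if dose_per_fx < 0 or n_fractions < 0:
        raise ValidationError("dose and fraction count must be non-negative")
    return n_fractions * dose_per_fx * (dose_per_fx + alpha_beta) / (2.0 + alpha_beta)
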