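"""Synthetic evaluation-study generator.

Emulates the statistical structure of a two-phase clinician-AI dose-decision
study: per-patient monotone TCP/NTCP curves, an AI recommendation at the
reward-maximizing grid dose, and parameterized evaluator behavior —

* evaluators are *believers* or *non-believers*; a non-believer never moves
  from the unassisted decision;
* a believer with influence weight ``w`` intends to shift toward the
  recommendation by ``w * (ai - un)``, but enacts the shift only when it
  exceeds ``adjustment_deadband`` (clinicians adjust "only if they find it
  necessary"): ``aia = un + w * (ai - un) + noise`` or ``aia = un``;
* unassisted decisions scatter around the standard of care with per-patient
  and per-evaluator offsets;
* trust on an individual recommendation decays with the pre-decision
  distance ``|ai - un|`` (deliberately *not* generated from the post-decision
  agreement, so a positive trust-agreement correlation is an emergent
  property, not baked in);
* confidence rises with closeness to the standard of care and, for the
  assisted decision, with trust;
* with a small probability an evaluator whose unassisted decision already
  matched the AI moves anyway, standing in for adjustments driven by the
  outcome-estimate display rather than the recommendation.

One global seed drives one named random stream per stage, so regenerating a
stage never perturbs the draws of the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .outcomes import OutcomePoint, reward
from .records import (
    DOSE_RESOLUTION,
    DOSE_TOL,
    CohortConfig,
    DecisionRecord,
    Disease,
    OutcomeCurve,
    TrustAnswers,
    ValidationError,
)

_STAGES = {"curves": 0, "ai": 1, "records": 2}

# Canonical answer combination attaining each 0-5 trust score under the
# 1+1+2+1 rubric (only the first option of each question carries points).
_ANSWERS_FOR_SCORE = {
    5: ("reasonable", "reasonable", "agree", "reasonable"),
    4: ("reasonable", "reasonable", "agree", "too_large"),
    3: ("reasonable", "unreasonable", "agree", "too_large"),
    2: ("unrealistic", "unreasonable", "agree", "too_large"),
    1: ("reasonable", "unreasonable", "go_higher", "too_large"),
    0: ("unrealistic", "unreasonable", "go_higher", "too_large"),
}


@dataclass(frozen=True)
class CurveParams:
    """Per-disease logistic dose-response parameter ranges.

    tcp(d) = floor + (1 - floor) * logistic((d - d50)/slope), similarly ntcp
    without a floor; both strictly increasing in dose. The HCC floor (0.9)
    emulates the high-event-rate bias of a model trained on a cohort with
    near-universal local control: TCP is projected high for every patient and
    changes only slightly over the dose range.
    """

    tcp_d50: tuple[float, float]
    tcp_slope: tuple[float, float]
    ntcp_d50: tuple[float, float]
    ntcp_slope: tuple[float, float]
    tcp_floor: float = 0.0

    @classmethod
    def default(cls, disease: Disease | str) -> "CurveParams":
        if Disease(disease) is Disease.NSCLC:
            return cls(
                tcp_d50=(1.8, 2.8), tcp_slope=(0.4, 0.8),
                ntcp_d50=(3.2, 5.0), ntcp_slope=(0.6, 1.2), tcp_floor=0.0,
            )
        return cls(
            tcp_d50=(2.0, 5.0), tcp_slope=(1.0, 2.0),
            ntcp_d50=(9.0, 14.0), ntcp_slope=(1.5, 3.0), tcp_floor=0.9,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one synthetic study arm.

    ``dose_resolution`` quantizes generated decisions (0 disables
    quantization, used by the idealized zero-noise configurations where
    fractional-weight adjustments must stay exact). All noise SDs are in
    Gy/fx on the dose scale or points on the 0-5 scales.
    """

    cohort: CohortConfig
    seed: int = 0
    nonbeliever_fraction: float = 0.0
    influence_weight_mean: float = 0.6
    influence_weight_sd: float = 0.15
    adjustment_deadband: float = 0.45
    decision_noise_sd: float = 0.3
    aia_noise_sd: float = 0.1
    un_soc_sd: float = 0.12
    evaluator_bias_sd: float = 0.35
    trust_slope: float = 1.5
    trust_noise_sd: float = 0.7
    conf_base: float = 3.5
    conf_closeness_gain: float = 1.2
    conf_trust_gain: float = 0.3
    conf_noise_sd: float = 0.7
    rtoe_bypass_probability: float = 0.1
    rtoe_shift: float = 0.3
    ai_jitter_sd: float = 0.1
    ai_sem_range: tuple[float, float] = (0.05, 0.3)
    curve_sem: float = 0.02
    dose_resolution: float = DOSE_RESOLUTION
    curve_params: CurveParams = field(
        default_factory=lambda: CurveParams.default(Disease.NSCLC)
    )

    def __post_init__(self) -> None:
        for name in ("nonbeliever_fraction", "rtoe_bypass_probability"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in (
            "influence_weight_sd", "decision_noise_sd", "aia_noise_sd",
            "un_soc_sd", "evaluator_bias_sd", "trust_noise_sd",
            "conf_noise_sd", "ai_jitter_sd", "curve_sem", "dose_resolution",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @classmethod
    def default(cls, disease: Disease | str, seed: int = 0) -> "SimulationConfig":
        """Study-condition defaults: cohort sizes 8x9 (NSCLC) / 9x8 (HCC);
        non-believer rate 2/9 for NSCLC and 0 for HCC (the study's two
        zero-adjustment evaluations both occurred in the NSCLC arm)."""
        disease = Disease(disease)
        cohort = CohortConfig.default(disease)
        if disease is Disease.NSCLC:
            return cls(cohort=cohort, seed=seed, nonbeliever_fraction=2.0 / 9.0,
                       curve_params=CurveParams.default(disease))
        return cls(
            cohort=cohort, seed=seed, nonbeliever_fraction=0.0,
            influence_weight_mean=0.5,
            adjustment_deadband=3.0, decision_noise_sd=1.0,
            aia_noise_sd=0.6, un_soc_sd=0.5, evaluator_bias_sd=1.2,
            trust_slope=0.35, conf_closeness_gain=0.25, rtoe_shift=1.0,
            ai_jitter_sd=0.3, ai_sem_range=(0.2, 1.0),
            curve_params=CurveParams.default(disease),
        )

    @classmethod
    def idealized(
        cls, disease: Disease | str, influence_weight: float,
        nonbeliever_fraction: float = 0.0, seed: int = 0,
    ) -> "SimulationConfig":
        """Noise-free variant for analytic checks: deterministic influence
        weight, no decision/trust/confidence noise, no recommendation jitter,
        no outcome-driven bypass, continuous (unquantized) doses."""
        base = cls.default(disease, seed=seed)
        return dataclasses.replace(
            base,
            nonbeliever_fraction=nonbeliever_fraction,
            influence_weight_mean=influence_weight,
            influence_weight_sd=0.0,
            adjustment_deadband=0.0,
            decision_noise_sd=0.0,
            aia_noise_sd=0.0,
            trust_noise_sd=0.0,
            conf_noise_sd=0.0,
            ai_jitter_sd=0.0,
            rtoe_bypass_probability=0.0,
            dose_resolution=0.0,
        )


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


def _round_half_away(x: float) -> float:
    return float(np.sign(x) * np.floor(np.abs(x) + 0.5))


def _quantize(dose: float, config: SimulationConfig) -> float:
    lo, hi = config.cohort.dose_min, config.cohort.dose_max
    dose = min(max(dose, lo), hi)
    res = config.dose_resolution
    if res > 0:
        dose = round(round(dose / res) * res, 10)
        dose = min(max(dose, lo), hi)
    return dose


def _level(x: float) -> int:
    return int(min(max(_round_half_away(x), 0), 5))


def dose_grid(cohort: CohortConfig, resolution: float = DOSE_RESOLUTION) -> np.ndarray:
    n = int(round((cohort.dose_max - cohort.dose_min) / resolution)) + 1
    return np.round(cohort.dose_min + resolution * np.arange(n), 10)


def generate_curves(config: SimulationConfig) -> list[OutcomeCurve]:
    """Patient-specific strictly increasing logistic TCP/NTCP curves sampled
    on the cohort dose grid; SEM columns are a small constant."""
    p = config.curve_params
    for lo, hi in (p.tcp_d50, p.tcp_slope, p.ntcp_d50, p.ntcp_slope):
        if not lo <= hi:
            raise ValidationError("degenerate curve parameter range")
    if p.tcp_slope[0] <= 0 or p.ntcp_slope[0] <= 0:
        raise ValidationError("slopes must be positive")
    if not 0 <= p.tcp_floor < 1:
        raise ValidationError("tcp_floor must be in [0, 1)")
    rng = _rng(config, "curves")
    grid = dose_grid(config.cohort)
    curves = []
    for i in range(config.cohort.n_patients):
        tcp_d50 = rng.uniform(*p.tcp_d50)
        tcp_slope = rng.uniform(*p.tcp_slope)
        ntcp_d50 = rng.uniform(*p.ntcp_d50)
        ntcp_slope = rng.uniform(*p.ntcp_slope)
        tcp = p.tcp_floor + (1 - p.tcp_floor) * expit((grid - tcp_d50) / tcp_slope)
        ntcp = expit((grid - ntcp_d50) / ntcp_slope)
        sem = np.full_like(grid, config.curve_sem)
        curves.append(
            OutcomeCurve(
                patient_id=f"P{i + 1}",
                disease=config.cohort.disease,
                doses=grid,
                tcp_mean=tcp,
                tcp_sem=sem,
                ntcp_mean=ntcp,
                ntcp_sem=sem,
            )
        )
    return curves


@dataclass(frozen=True)
class AiRecommendation:
    patient_id: str
    dose: float
    sem: float


def generate_ai_recommendations(
    curves: Sequence[OutcomeCurve], config: SimulationConfig
) -> dict[str, AiRecommendation]:
    """AI dose per patient: the grid dose maximizing the cohort reward
    (first/lowest dose on ties), plus jitter for ensemble spread, clipped and
    quantized; SEM drawn uniformly from the configured range."""
    rng = _rng(config, "ai")
    recs: dict[str, AiRecommendation] = {}
    for curve in curves:
        rewards = np.array(
            [
                reward(OutcomePoint(t, nt), config.cohort)
                for t, nt in zip(curve.tcp_mean, curve.ntcp_mean)
            ]
        )
        best = float(curve.doses[int(np.argmax(rewards))])
        # Scale a unit draw so toggling jitter off leaves the stream aligned.
        dose = _quantize(best + rng.normal() * config.ai_jitter_sd, config)
        sem = float(rng.uniform(*config.ai_sem_range))
        recs[curve.patient_id] = AiRecommendation(curve.patient_id, dose, sem)
    return recs


@dataclass(frozen=True)
class EvaluatorTruth:
    evaluator_id: str
    believer: bool
    influence_weight: float
    bias: float


@dataclass(frozen=True)
class SimulatedStudy:
    config: SimulationConfig
    curves: list[OutcomeCurve]
    ai: dict[str, AiRecommendation]
    records: list[DecisionRecord]
    truth: list[EvaluatorTruth]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.truth])


def generate_records(
    curves: Sequence[OutcomeCurve],
    ai: dict[str, AiRecommendation],
    config: SimulationConfig,
) -> tuple[list[DecisionRecord], list[EvaluatorTruth]]:
    """Decision records for every evaluator x patient cell, plus the
    generating truth (believer flags, influence weights) for parameter
    recovery checks. Fully determined by the config seed."""
    rng = _rng(config, "records")
    cohort = config.cohort
    k, n = cohort.n_evaluators, cohort.n_patients

    truth = []
    for j in range(k):
        believer = bool(rng.random() >= config.nonbeliever_fraction)
        w = float(np.clip(
            config.influence_weight_mean + rng.normal() * config.influence_weight_sd,
            0.0, 1.0))
        bias = float(rng.normal() * config.evaluator_bias_sd)
        truth.append(EvaluatorTruth(f"E{j + 1}", believer, w, bias))

    patient_offset = {
        c.patient_id: float(rng.normal(0.0, config.un_soc_sd)) for c in curves
    }

    def noise(sd: float) -> float:
        # Always consume a draw so toggling a noise term off does not shift
        # every later draw in the stream.
        z = rng.normal()
        return z * sd

    records: list[DecisionRecord] = []
    for ev in truth:
        for curve in curves:
            rec_ai = ai[curve.patient_id]
            un = _quantize(
                cohort.soc_dose + patient_offset[curve.patient_id] + ev.bias
                + noise(config.decision_noise_sd),
                config,
            )
            trust = _level(
                5.0 - config.trust_slope * abs(rec_ai.dose - un)
                + noise(config.trust_noise_sd)
            )
            aia_noise = noise(config.aia_noise_sd)
            bypass_u = rng.random()
            bypass_sign = 1.0 if rng.random() < 0.5 else -1.0
            aia_raw = un
            if ev.believer:
                near_ai = abs(rec_ai.dose - un) <= DOSE_TOL
                shift = ev.influence_weight * (rec_ai.dose - un)
                if near_ai and bypass_u < config.rtoe_bypass_probability:
                    # Already matching the AI, yet moving: an adjustment
                    # driven by the outcome-estimate display alone.
                    aia_raw = un + bypass_sign * config.rtoe_shift
                elif abs(shift) >= config.adjustment_deadband:
                    aia_raw = un + shift + aia_noise
            aia = _quantize(aia_raw, config)
            un_conf = _level(
                config.conf_base
                + config.conf_closeness_gain * (-abs(un - cohort.soc_dose))
                + noise(config.conf_noise_sd)
            )
            aia_conf = _level(
                config.conf_base
                + config.conf_closeness_gain * (-abs(aia - cohort.soc_dose))
                + config.conf_trust_gain * (trust - 2.5)
                + noise(config.conf_noise_sd)
            )
            records.append(
                DecisionRecord(
                    evaluator_id=ev.evaluator_id,
                    patient_id=curve.patient_id,
                    disease=cohort.disease,
                    un=un,
                    un_conf=un_conf,
                    aia=aia,
                    aia_conf=aia_conf,
                    ai=rec_ai.dose,
                    ai_sem=rec_ai.sem,
                    trust_answers=TrustAnswers(*_ANSWERS_FOR_SCORE[trust]),
                    trust_level=trust,
                )
            )
    return records, truth


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run all three stages: curves -> AI recommendations -> records."""
    curves = generate_curves(config)
    ai = generate_ai_recommendations(curves, config)
    records, truth = generate_records(curves, ai, config)
    return SimulatedStudy(config=config, curves=curves, ai=ai,
                          records=records, truth=truth)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable provenance view of a config."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, Disease):
            return obj.value
        return obj

    return _clean(dataclasses.asdict(config))
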