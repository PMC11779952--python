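"""Data model and file I/O for evaluation records and outcome curves.

One *decision record* is the unit of the study: a single evaluator deciding a
daily dose fractionation (Gy/fx) for a single patient, first unassisted
(``un``) and then after seeing the AI recommendation (``aia``), together with
confidence levels, the AI-recommended dose (ensemble mean +/- SEM) and the
four trust-question answers that build the 0-5 AI trust level.

Doses are treated at a resolution of 0.1 Gy/fx throughout; equality between
doses elsewhere in the package means agreement within half that grain.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("collabrt")

#: Grain at which doses are stored and compared (Gy/fx).
DOSE_RESOLUTION = 0.1
#: Default equality tolerance: half the dose resolution, so identically
#: entered doses compare equal and any visible change counts as an adjustment.
DOSE_TOL = DOSE_RESOLUTION / 2.0


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A row or value violates the data contract; message names the location."""


class Disease(str, enum.Enum):
    NSCLC = "NSCLC"
    HCC = "HCC"


class OutcomeReasonable(str, enum.Enum):
    REASONABLE = "reasonable"
    UNREALISTIC = "unrealistic"


class OutcomeUncertainty(str, enum.Enum):
    REASONABLE = "reasonable"
    UNREASONABLE = "unreasonable"


class RecommendationView(str, enum.Enum):
    AGREE = "agree"
    GO_HIGHER = "go_higher"
    GO_LOWER = "go_lower"


class RecommendationUncertainty(str, enum.Enum):
    REASONABLE = "reasonable"
    TOO_SMALL = "too_small"
    TOO_LARGE = "too_large"


@dataclass(frozen=True)
class TrustAnswers:
    """Answers to the four AI-trust multiple-choice questions.

    Two questions concern the outcome estimate (reasonableness, uncertainty),
    two the dose recommendation (agreement, uncertainty). Scoring is handled
    by :func:`collabrt.metrics.trust_score`.
    """

    outcome_reasonable: OutcomeReasonable
    outcome_uncertainty: OutcomeUncertainty
    recommendation_view: RecommendationView
    recommendation_uncertainty: RecommendationUncertainty

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "outcome_reasonable", OutcomeReasonable(self.outcome_reasonable)
        )
        object.__setattr__(
            self, "outcome_uncertainty", OutcomeUncertainty(self.outcome_uncertainty)
        )
        object.__setattr__(
            self, "recommendation_view", RecommendationView(self.recommendation_view)
        )
        object.__setattr__(
            self,
            "recommendation_uncertainty",
            RecommendationUncertainty(self.recommendation_uncertainty),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Disease-level constants of one study arm.

    ``reward_tcp_high``/``reward_ntcp_low`` are the clinical-goal thresholds of
    the top reward case (+2): NSCLC aims for population local control > 70%
    with toxicity < 17.2%; HCC, with its high event rate, for TCP > 90% with
    NTCP < 25%.
    """

    disease: Disease
    dose_min: float
    dose_max: float
    soc_dose: float
    adaptation_fractions: int
    reward_tcp_high: float
    reward_ntcp_low: float
    n_patients: int
    n_evaluators: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease", Disease(self.disease))
        if not (self.dose_min < self.soc_dose < self.dose_max):
            raise ValidationError(
                f"require dose_min < soc_dose < dose_max, got "
                f"({self.dose_min}, {self.soc_dose}, {self.dose_max})"
            )

    def contains(self, dose: float) -> bool:
        # Small slack so grid endpoints survive float round-trips.
        return self.dose_min - 1e-9 <= dose <= self.dose_max + 1e-9

    @classmethod
    def default(cls, disease: Disease | str) -> "CohortConfig":
        disease = Disease(disease)
        if disease is Disease.NSCLC:
            return cls(
                disease=Disease.NSCLC,
                dose_min=1.5,
                dose_max=4.0,
                soc_dose=2.0,
                adaptation_fractions=10,
                reward_tcp_high=0.70,
                reward_ntcp_low=0.172,
                n_patients=8,
                n_evaluators=9,
            )
        return cls(
            disease=Disease.HCC,
            dose_min=1.0,
            dose_max=15.0,
            soc_dose=10.0,
            adaptation_fractions=2,
            reward_tcp_high=0.90,
            reward_ntcp_low=0.25,
            n_patients=9,
            n_evaluators=8,
        )


@dataclass(frozen=True)
class DecisionRecord:
    """One evaluator x patient evaluation unit."""

    evaluator_id: str
    patient_id: str
    disease: Disease
    un: float
    un_conf: int
    aia: float
    aia_conf: int
    ai: float
    ai_sem: float
    trust_answers: TrustAnswers
    trust_level: int
    remark_un: str = ""
    remark_aia: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease", Disease(self.disease))
        for name in ("un_conf", "aia_conf", "trust_level"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 5):
                raise ValidationError(f"{name}={v!r} not an integer in 0..5")
        if self.ai_sem < 0:
            raise ValidationError(f"ai_sem={self.ai_sem} must be non-negative")

    def validate_doses(self, cohort: CohortConfig) -> None:
        for name in ("un", "aia", "ai"):
            d = getattr(self, name)
            if not cohort.contains(d):
                raise ValidationError(
                    f"{name}={d} outside [{cohort.dose_min}, {cohort.dose_max}] "
                    f"for {cohort.disease.value}"
                )


@dataclass(frozen=True)
class OutcomeCurve:
    """Per-patient TCP/NTCP estimates (mean, SEM) on a dose grid."""

    patient_id: str
    disease: Disease
    doses: np.ndarray
    tcp_mean: np.ndarray
    tcp_sem: np.ndarray
    ntcp_mean: np.ndarray
    ntcp_sem: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease", Disease(self.disease))
        for name in ("doses", "tcp_mean", "tcp_sem", "ntcp_mean", "ntcp_sem"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.doses.size
        for name in ("tcp_mean", "tcp_sem", "ntcp_mean", "ntcp_sem"):
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"curve {self.patient_id}: {name} length != dose grid length"
                )
        if n < 2 or not np.all(np.diff(self.doses) > 0):
            raise ValidationError(
                f"curve {self.patient_id}: dose grid must be strictly increasing "
                "with at least two points"
            )
        for name in ("tcp_mean", "ntcp_mean"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValidationError(f"curve {self.patient_id}: {name} outside [0, 1]")
        for name in ("tcp_sem", "ntcp_sem"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"curve {self.patient_id}: {name} negative")


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "disease",
    "evaluator_id",
    "patient_id",
    "un_gy_fx",
    "un_conf",
    "aia_gy_fx",
    "aia_conf",
    "ai_mean_gy_fx",
    "ai_sem_gy_fx",
    "trust_q1",
    "trust_q2",
    "trust_q3",
    "trust_q4",
    "trust_level",
    "remark_un",
    "remark_aia",
]

CURVE_COLUMNS = [
    "disease",
    "patient_id",
    "dose_gy_fx",
    "tcp_mean",
    "tcp_sem",
    "ntcp_mean",
    "ntcp_sem",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_records(path: str | Path, cohort: CohortConfig) -> list[DecisionRecord]:
    """Read and validate a long-format decision-record CSV.

    Every row either yields a validated :class:`DecisionRecord` or raises a
    located error; rows are never dropped silently. A stored ``trust_level``
    inconsistent with its answers is kept (the stored level is authoritative)
    but logged as a warning.
    """
    from .metrics import trust_score  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, dtype={"evaluator_id": str, "patient_id": str},
                     float_precision="round_trip")
    _require_columns(df, [c for c in RECORD_COLUMNS if not c.startswith("remark")], path)
    records: list[DecisionRecord] = []
    for idx, row in df.iterrows():
        loc = f"{path} row {idx + 2}"  # 1-based with header line
        if Disease(str(row["disease"])) is not cohort.disease:
            raise ValidationError(f"{loc}: disease {row['disease']!r} does not match "
                                  f"cohort {cohort.disease.value}")
        try:
            answers = TrustAnswers(
                row["trust_q1"], row["trust_q2"], row["trust_q3"], row["trust_q4"]
            )
            rec = DecisionRecord(
                evaluator_id=str(row["evaluator_id"]),
                patient_id=str(row["patient_id"]),
                disease=cohort.disease,
                un=float(row["un_gy_fx"]),
                un_conf=int(row["un_conf"]),
                aia=float(row["aia_gy_fx"]),
                aia_conf=int(row["aia_conf"]),
                ai=float(row["ai_mean_gy_fx"]),
                ai_sem=float(row["ai_sem_gy_fx"]),
                trust_answers=answers,
                trust_level=int(row["trust_level"]),
                remark_un=_opt_str(row.get("remark_un")),
                remark_aia=_opt_str(row.get("remark_aia")),
            )
            rec.validate_doses(cohort)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{loc}: {exc}") from exc
        if trust_score(rec.trust_answers) != rec.trust_level:
            logger.warning(
                "%s: stored trust_level %d inconsistent with answers (score %d); "
                "stored level kept",
                loc, rec.trust_level, trust_score(rec.trust_answers),
            )
        records.append(rec)
    if not records:
        logger.warning("%s: no data rows (header only)", path)
    logger.info("read %d decision records from %s", len(records), path)
    return records


def _opt_str(v: object) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    return str(v)


def write_records(records: Iterable[DecisionRecord], path: str | Path) -> None:
    """Write records to the documented CSV schema (round-trips exactly)."""
    rows = []
    for r in records:
        rows.append(
            {
                "disease": r.disease.value,
                "evaluator_id": r.evaluator_id,
                "patient_id": r.patient_id,
                "un_gy_fx": r.un,
                "un_conf": r.un_conf,
                "aia_gy_fx": r.aia,
                "aia_conf": r.aia_conf,
                "ai_mean_gy_fx": r.ai,
                "ai_sem_gy_fx": r.ai_sem,
                "trust_q1": r.trust_answers.outcome_reasonable.value,
                "trust_q2": r.trust_answers.outcome_uncertainty.value,
                "trust_q3": r.trust_answers.recommendation_view.value,
                "trust_q4": r.trust_answers.recommendation_uncertainty.value,
                "trust_level": r.trust_level,
                "remark_un": r.remark_un,
                "remark_aia": r.remark_aia,
            }
        )
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_curves(path: str | Path, cohort: CohortConfig) -> list[OutcomeCurve]:
    """Read per-patient TCP/NTCP curves from the long-format curves CSV.

    Rows may arrive unsorted; the grid of each patient is sorted internally
    (with a warning). Duplicate (patient, dose) rows and probabilities outside
    [0, 1] are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str},
                     float_precision="round_trip")
    _require_columns(df, CURVE_COLUMNS, path)
    curves: list[OutcomeCurve] = []
    for pid, g in df.groupby("patient_id", sort=True):
        doses = g["dose_gy_fx"].to_numpy(float)
        if np.unique(np.round(doses / DOSE_RESOLUTION)).size != doses.size:
            raise ValidationError(f"{path}: duplicate dose grid point for patient {pid}")
        if not np.all(np.diff(doses) > 0):
            logger.warning("%s: dose grid for patient %s not sorted; sorting", path, pid)
            g = g.sort_values("dose_gy_fx")
        if doses.min() > cohort.dose_min + 1e-9 or doses.max() < cohort.dose_max - 1e-9:
            logger.warning(
                "%s: grid for patient %s spans [%g, %g], short of the cohort "
                "range [%g, %g]; doses outside it cannot be scored",
                path, pid, doses.min(), doses.max(),
                cohort.dose_min, cohort.dose_max,
            )
        curves.append(
            OutcomeCurve(
                patient_id=str(pid),
                disease=cohort.disease,
                doses=g["dose_gy_fx"].to_numpy(float),
                tcp_mean=g["tcp_mean"].to_numpy(float),
                tcp_sem=g["tcp_sem"].to_numpy(float),
                ntcp_mean=g["ntcp_mean"].to_numpy(float),
                ntcp_sem=g["ntcp_sem"].to_numpy(float),
            )
        )
    logger.info("read %d outcome curves from %s", len(curves), path)
    return curves


def write_curves(curves: Iterable[OutcomeCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for i in range(c.doses.size):
            rows.append(
                {
                    "disease": c.disease.value,
                    "patient_id": c.patient_id,
                    "dose_gy_fx": c.doses[i],
                    "tcp_mean": c.tcp_mean[i],
                    "tcp_sem": c.tcp_sem[i],
                    "ntcp_mean": c.ntcp_mean[i],
                    "ntcp_sem": c.ntcp_sem[i],
                }
            )
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the statistical pipeline.

    tolerance
        Dose-equality tolerance (Gy/fx) used for adjustment flags and the
        influence truth table; default half the 0.1 Gy/fx storage grain.
    max_exact_n
        Randomization tests enumerate all 2^n sign patterns up to this n
        (the study's group sizes, 8-9, are always exact); beyond it, Monte
        Carlo with ``n_resamples`` draws seeded by ``seed``.
    """

    tolerance: float = DOSE_TOL
    confidence: float = 0.95
    max_exact_n: int = 20
    n_resamples: int = 9999
    seed: int = 0
    alpha_beta: float = 10.0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisOptions":
        payload = _load_config_file(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise SchemaError(f"{path}: unknown option(s): {', '.join(sorted(unknown))}")
        return cls(**payload)


def _load_config_file(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: config file must hold a mapping")
    return payload
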