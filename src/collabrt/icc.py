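"""McGraw & Wong two-way random-effects intraclass correlation.

The decision matrix is n patients (rows) x k evaluators (columns); both are
treated as random draws from larger pools, so the two-way random-effects
model d_ij = mu + a_i + b_j + e_ij applies. From the two-way ANOVA mean
squares — MSR (rows/patients), MSC (columns/evaluators), MSE (residual) —
four coefficients are formed:

    ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(C,k) = (MSR - MSE) / MSR
    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

Consistency (C) ignores systematic per-evaluator offsets; Absolute Agreement
(A) penalizes them. Confidence intervals follow McGraw & Wong: exact F bounds
for C, Satterthwaite-approximated denominator degrees of freedom for A. The
p-value is the one-sided F-test of H0: icc = 0 against icc > 0 (for the A
variants the F statistic MSR/MSE is referred to the Satterthwaite df, the
convention of the standard inter-rater implementations). Negative estimates
are reported as computed, never truncated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .records import CohortConfig, DecisionRecord, ValidationError


class IccType(str, enum.Enum):
    CONSISTENCY = "C"
    AGREEMENT = "A"


class IccUnit(str, enum.Enum):
    SINGLE = "single"
    AVERAGE = "average"


@dataclass(frozen=True)
class IccResult:
    icc_type: IccType
    unit: IccUnit
    value: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: float
    df2: float
    p_value: float
    n: int
    k: int
    confidence: float
    degenerate: bool = False

    @property
    def label(self) -> str:
        u = "1" if self.unit is IccUnit.SINGLE else str(self.k)
        return f"ICC({self.icc_type.value},{u})"


def _mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows, columns, residual) of a complete
    n x k matrix."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_random(
    matrix: Sequence[Sequence[float]] | np.ndarray,
    icc_type: IccType | str,
    unit: IccUnit | str,
    confidence: float = 0.95,
) -> IccResult:
    """One McGraw & Wong ICC variant of an n x k decision matrix.

    Rows are patients, columns evaluators; the matrix must be complete with
    n >= 2 and k >= 2. Zero residual variance (all columns identical up to
    the model) yields value 1 with a degenerate CI, flagged.
    """
    icc_type = IccType(icc_type)
    unit = IccUnit(unit)
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("matrix must be 2-d with n >= 2 patients, k >= 2 raters")
    if np.isnan(m).any():
        raise ValidationError("matrix has missing cells; complete it before calling")
    if not (0 < confidence < 1):
        raise ValidationError("confidence must be in (0, 1)")
    n, k = m.shape
    msr, msc, mse = _mean_squares(m)
    alpha = 1.0 - confidence
    df1 = n - 1.0
    df2_resid = (n - 1.0) * (k - 1.0)

    if mse == 0.0:
        # Zero residual variance: point estimates are still well defined by
        # the mean-square formulas, but the F statistic diverges and the CI
        # collapses; flag the whole result.
        if msr == 0.0:
            value = float("nan")
        elif icc_type is IccType.CONSISTENCY:
            value = 1.0
        elif unit is IccUnit.SINGLE:
            value = msr / (msr + (k / n) * msc)
        else:
            value = msr / (msr + msc / n)
        return IccResult(
            icc_type=icc_type, unit=unit, value=float(value),
            ci_low=float(value), ci_high=float(value),
            f_value=float("inf") if msr > 0 else float("nan"),
            df1=df1, df2=df2_resid, p_value=0.0 if msr > 0 else 1.0,
            n=n, k=k, confidence=confidence, degenerate=True,
        )

    f_obs = msr / mse

    if icc_type is IccType.CONSISTENCY:
        value_single = (msr - mse) / (msr + (k - 1) * mse)
        fl = f_obs / f_dist.ppf(1 - alpha / 2, df1, df2_resid)
        fu = f_obs * f_dist.ppf(1 - alpha / 2, df2_resid, df1)
        if unit is IccUnit.SINGLE:
            value = value_single
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            value = (msr - mse) / msr
            lo = 1 - 1 / fl
            hi = 1 - 1 / fu
        df2 = df2_resid
    else:
        value_single = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        # Satterthwaite df for the A-variant bounds and test.
        fj = msc / mse
        vn = df2_resid * (k * value_single * fj + n * (1 + (k - 1) * value_single)
                          - k * value_single) ** 2
        vd = (df1 * k**2 * value_single**2 * fj**2
              + (n * (1 + (k - 1) * value_single) - k * value_single) ** 2)
        v = vn / vd
        f_hi = f_dist.ppf(1 - alpha / 2, df1, v)
        f_lo = f_dist.ppf(1 - alpha / 2, v, df1)
        lo1 = n * (msr - f_hi * mse) / (
            f_hi * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_lo * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_lo * msr
        )
        if unit is IccUnit.SINGLE:
            value, lo, hi = value_single, lo1, hi1
        else:
            value = (msr - mse) / (msr + (msc - mse) / n)
            lo = lo1 * k / (1 + lo1 * (k - 1))
            hi = hi1 * k / (1 + hi1 * (k - 1))
        df2 = v

    p = float(f_dist.sf(f_obs, df1, df2))
    return IccResult(
        icc_type=icc_type, unit=unit, value=float(value),
        ci_low=float(lo), ci_high=float(hi),
        f_value=float(f_obs), df1=df1, df2=float(df2), p_value=p,
        n=n, k=k, confidence=confidence,
    )


ALL_VARIANTS: tuple[tuple[IccType, IccUnit], ...] = (
    (IccType.CONSISTENCY, IccUnit.SINGLE),
    (IccType.AGREEMENT, IccUnit.SINGLE),
    (IccType.CONSISTENCY, IccUnit.AVERAGE),
    (IccType.AGREEMENT, IccUnit.AVERAGE),
)


def decision_matrix(
    records: Sequence[DecisionRecord], which: str
) -> pd.DataFrame:
    """Pivot records into the n x k (patients x evaluators) dose matrix for
    ``which`` in {'un', 'aia'}; errors on duplicate or missing cells."""
    if which not in ("un", "aia"):
        raise ValidationError("which must be 'un' or 'aia'")
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "evaluator_id": [r.evaluator_id for r in records],
            "dose": [getattr(r, which) for r in records],
        }
    )
    dup = df.duplicated(["patient_id", "evaluator_id"])
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "evaluator_id"]].to_records(index=False)
        raise ValidationError(f"duplicate evaluator x patient cells: {list(pairs)}")
    wide = df.pivot(index="patient_id", columns="evaluator_id", values="dose")
    if wide.isna().any().any():
        missing = [
            (p, e)
            for p in wide.index
            for e in wide.columns
            if pd.isna(wide.at[p, e])
        ]
        raise ValidationError(f"incomplete design; missing cells: {missing}")
    return wide.sort_index(axis=0).sort_index(axis=1)


def icc_comparison(
    records: Sequence[DecisionRecord],
    cohort: CohortConfig,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """All four ICC variants for the unassisted and AI-assisted matrices.

    Returns the eight results in a comparison-table layout: one row per
    (phase, variant) with value, CI bounds, F, df, and one-sided p.
    """
    rows = []
    for phase in ("un", "aia"):
        matrix = decision_matrix(records, phase).to_numpy()
        for icc_type, unit in ALL_VARIANTS:
            res = icc_two_way_random(matrix, icc_type, unit, confidence)
            rows.append(
                {
                    "disease": cohort.disease.value,
                    "phase": "unassisted" if phase == "un" else "ai_assisted",
                    "variant": res.label,
                    "icc_type": res.icc_type.value,
                    "unit": res.unit.value,
                    "value": res.value,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "f_value": res.f_value,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p_value": res.p_value,
                    "n_patients": res.n,
                    "k_evaluators": res.k,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)
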