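"""Hypothesis-testing machinery.

The central test is a matched-pair randomization t-test: under the null of no
AI influence the sign of each paired difference ``d = un - aia`` is
exchangeable, so the null distribution of the one-sample t statistic is built
by flipping the sign of each difference independently. All 2^n sign patterns
are enumerated when n is small (always the case for the study's per-evaluator
and per-patient groups of 8-9 pairs); otherwise random sign patterns are
drawn, with the observed pattern counted among them so the p-value can never
be zero.

Correlation coefficients (Spearman mid-rank, Pearson) and their two-sided
t-approximation p-values are delegated to scipy.stats; covariance ellipses
come from an eigendecomposition of the 2x2 sample covariance scaled by the
chi-square quantile.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .records import ValidationError

_TIE_EPS = 1e-12  # |t*| >= |t_obs| comparisons tolerate float jitter this large


class TestMethod(str, enum.Enum):
    EXACT = "exact"
    MONTE_CARLO = "monte_carlo"


def sig_code(p: float) -> str:
    """Standard significance code with strict thresholds:
    *** p<0.001, ** p<0.01, * p<0.05, . p<0.1, N.S otherwise."""
    if not (0 <= p <= 1):
        raise ValidationError(f"p={p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "N.S"


@dataclass(frozen=True)
class RandTestResult:
    t_observed: float
    p_value: float
    method: TestMethod
    n: int
    n_resamples: int
    seed: int | None
    degenerate: bool

    @property
    def sig_code(self) -> str:
        return sig_code(self.p_value)


def _t_from_sums(s: np.ndarray, ssq: float, n: int) -> np.ndarray:
    """One-sample t for sign-flipped differences given signed sums.

    Sign flips leave sum(d_i^2) unchanged, so each pattern's t depends only on
    its signed sum s: t = m / sqrt(var/n) with m = s/n and
    var = (ssq - n m^2)/(n-1). A zero-variance pattern gives +/-inf (or 0 when
    the mean is also 0), matching the limit of the statistic.
    """
    m = s / n
    if n == 1:
        var = np.zeros_like(m)
    else:
        var = np.maximum(ssq - n * m**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
        zero_var = np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0))
    return np.where(var == 0, zero_var, t)


def paired_randomization_t(
    x: Sequence[float],
    y: Sequence[float],
    max_exact_n: int = 20,
    n_resamples: int = 9999,
    seed: int | None = None,
) -> RandTestResult:
    """Two-sided matched-pair randomization t-test of H0: x - y = 0.

    Exact enumeration of all 2^n sign patterns when ``n <= max_exact_n``
    (p = plain proportion of patterns with |t*| >= |t_obs|; the observed
    pattern is one of them, so p >= 2^-n). Otherwise Monte Carlo with the
    add-one rule p = (count + 1)/(R + 1), ``seed`` required.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValidationError("paired samples must be equal-length 1-d, n >= 1")
    d = x - y
    n = d.size
    if np.all(d == 0):
        return RandTestResult(
            t_observed=float("nan"), p_value=1.0, method=TestMethod.EXACT,
            n=n, n_resamples=0, seed=None, degenerate=True,
        )
    ssq = float(np.sum(d**2))
    t_obs = float(_t_from_sums(np.array([d.sum()]), ssq, n)[0])
    threshold = abs(t_obs) - _TIE_EPS

    if n <= max_exact_n:
        total = 1 << n
        count = 0
        bits = np.arange(n)
        chunk = 1 << min(n, 16)
        for start in range(0, total, chunk):
            patt = np.arange(start, min(start + chunk, total), dtype=np.int64)
            signs = 1.0 - 2.0 * ((patt[:, None] >> bits) & 1)
            t_star = _t_from_sums(signs @ d, ssq, n)
            count += int(np.sum(np.abs(t_star) >= threshold))
        return RandTestResult(
            t_observed=t_obs, p_value=count / total, method=TestMethod.EXACT,
            n=n, n_resamples=total, seed=None, degenerate=False,
        )

    if seed is None:
        raise ValidationError("seed is required for the Monte Carlo method")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
    t_star = _t_from_sums(signs @ d, ssq, n)
    count = int(np.sum(np.abs(t_star) >= threshold))
    return RandTestResult(
        t_observed=t_obs,
        p_value=(count + 1) / (n_resamples + 1),
        method=TestMethod.MONTE_CARLO,
        n=n,
        n_resamples=n_resamples,
        seed=seed,
        degenerate=False,
    )


class CorrelationKind(str, enum.Enum):
    SPEARMAN = "spearman"
    PEARSON = "pearson"


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    kind: CorrelationKind
    n: int
    degenerate: bool = False
    approximate: bool = False  # t-approximation flagged for very small n

    @property
    def sig_code(self) -> str:
        return sig_code(self.p_value) if not self.degenerate else "N.S"


def _check_pair(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("samples must be equal-length 1-d")
    if x.size < 3:
        raise ValidationError("n >= 3 required for a correlation p-value")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties) with two-sided p from
    the t transform on n - 2 degrees of freedom."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"),
                                 CorrelationKind.SPEARMAN, x.size, degenerate=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), CorrelationKind.SPEARMAN,
                             x.size, approximate=x.size < 10)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"),
                                 CorrelationKind.PEARSON, x.size, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), CorrelationKind.PEARSON, x.size)


@dataclass(frozen=True)
class CovarianceEllipse:
    """Confidence ellipse of a bivariate sample: center at the means, axes
    along the covariance eigenvectors, semi-axis lengths
    sqrt(lambda_i * chi2_2(confidence))."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_rad: float  # angle of the major axis from the x-axis
    confidence: float
    degenerate: bool


def covariance_ellipse(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> CovarianceEllipse:
    x, y = _check_pair(x, y)
    if not (0 < confidence < 1):
        raise ValidationError("confidence must be in (0, 1)")
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.maximum(evals, 0.0)
    scale = math.sqrt(sps.chi2.ppf(confidence, df=2))
    major, minor = math.sqrt(evals[1]) * scale, math.sqrt(evals[0]) * scale
    angle = math.atan2(evecs[1, 1], evecs[0, 1])
    degenerate = evals[1] == 0 or evals[0] <= 1e-12 * evals[1]
    return CovarianceEllipse(
        center=(float(x.mean()), float(y.mean())),
        semi_major=float(major),
        semi_minor=float(minor),
        orientation_rad=float(angle),
        confidence=confidence,
        degenerate=bool(degenerate),
    )
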