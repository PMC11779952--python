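import numpy as np
import pytest

from collabrt import (
    CohortConfig,
    DecisionRecord,
    Disease,
    OutcomeCurve,
    TrustAnswers,
)

TRUST_FULL = TrustAnswers("reasonable", "reasonable", "agree", "reasonable")


@pytest.fixture
def nsclc():
    return CohortConfig.default(Disease.NSCLC)


@pytest.fixture
def hcc():
    return CohortConfig.default(Disease.HCC)


@pytest.fixture
def make_record():
    """Factory for a valid NSCLC-range record with overridable fields."""

    def _make(**kw):
        base = dict(
            evaluator_id="E1",
            patient_id="P1",
            disease=Disease.NSCLC,
            un=2.0,
            un_conf=3,
            aia=2.5,
            aia_conf=4,
            ai=3.0,
            ai_sem=0.1,
            trust_answers=TRUST_FULL,
            trust_level=5,
        )
        base.update(kw)
        return DecisionRecord(**base)

    return _make


@pytest.fixture
def linear_curve():
    """Monotone toy curve on [1, 15]: tcp and ntcp linear in dose."""
    doses = np.linspace(1.0, 15.0, 15)
    return OutcomeCurve(
        patient_id="P1",
        disease=Disease.HCC,
        doses=doses,
        tcp_mean=np.linspace(0.1, 0.9, 15),
        tcp_sem=np.full(15, 0.01),
        ntcp_mean=np.linspace(0.05, 0.6, 15),
        ntcp_sem=np.full(15, 0.01),
    )
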