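import dataclasses

import numpy as np
import pytest

from collabrt import (
    Disease,
    SimulationConfig,
    adjustment_frequency,
    agreement,
    generate_ai_recommendations,
    generate_curves,
    generate_study,
    reward,
    spearman,
    trust_score,
)
from collabrt.outcomes import OutcomePoint
from collabrt.records import OutcomeCurve
from collabrt.simulate import CurveParams, dose_grid


def test_identical_config_reproduces_study_exactly():
    cfg = SimulationConfig.default(Disease.NSCLC, seed=123)
    a = generate_study(cfg)
    b = generate_study(cfg)
    assert a.records == b.records
    assert a.truth == b.truth
    for ca, cb in zip(a.curves, b.curves):
        np.testing.assert_array_equal(ca.tcp_mean, cb.tcp_mean)
        np.testing.assert_array_equal(ca.ntcp_mean, cb.ntcp_mean)


def test_named_streams_isolate_stages():
    """Changing a curve-only parameter must not perturb the evaluator truth
    or the unassisted decisions drawn from the records stream."""
    base = SimulationConfig.default(Disease.NSCLC, seed=5)
    alt = dataclasses.replace(base, curve_sem=0.005)
    sa, sb = generate_study(base), generate_study(alt)
    assert sa.truth == sb.truth
    assert [r.un for r in sa.records] == [r.un for r in sb.records]


@pytest.mark.parametrize("disease", ["NSCLC", "HCC"])
def test_curves_monotone_and_on_cohort_grid(disease):
    cfg = SimulationConfig.default(disease, seed=2)
    curves = generate_curves(cfg)
    assert len(curves) == cfg.cohort.n_patients
    for c in curves:
        assert np.all(np.diff(c.tcp_mean) >= 0)
        assert np.all(np.diff(c.ntcp_mean) >= 0)
        assert c.doses[0] == cfg.cohort.dose_min
        assert c.doses[-1] == cfg.cohort.dose_max


def test_hcc_curves_respect_tcp_floor():
    cfg = SimulationConfig.default(Disease.HCC, seed=3)
    assert min(c.tcp_mean.min() for c in generate_curves(cfg)) >= 0.9


def test_sharp_slope_limit_approaches_step():
    cfg = dataclasses.replace(
        SimulationConfig.default(Disease.NSCLC, seed=1),
        curve_params=CurveParams(
            tcp_d50=(2.5, 2.5), tcp_slope=(1e-4, 1e-4),
            ntcp_d50=(3.5, 3.5), ntcp_slope=(0.5, 1.0),
        ),
    )
    curve = generate_curves(cfg)[0]
    tcp = curve.tcp_mean
    below = curve.doses < 2.45
    above = curve.doses > 2.55
    assert np.all(tcp[below] < 1e-6)
    assert np.all(tcp[above] > 1 - 1e-6)


def test_ai_recommendation_is_reward_argmax(hcc):
    cfg = dataclasses.replace(SimulationConfig.default(Disease.HCC, seed=6),
                              ai_jitter_sd=0.0)
    curves = generate_curves(cfg)
    recs = generate_ai_recommendations(curves, cfg)
    for c in curves:
        rewards = [
            reward(OutcomePoint(t, nt), cfg.cohort)
            for t, nt in zip(c.tcp_mean, c.ntcp_mean)
        ]
        best = c.doses[int(np.argmax(rewards))]  # brute-force grid argmax
        assert recs[c.patient_id].dose == pytest.approx(best)
        lo, hi = cfg.ai_sem_range
        assert lo <= recs[c.patient_id].sem <= hi


def test_flat_tcp_rising_ntcp_recommends_minimum_dose(hcc):
    cfg = dataclasses.replace(SimulationConfig.default(Disease.HCC, seed=6),
                              ai_jitter_sd=0.0)
    grid = dose_grid(cfg.cohort)
    curve = OutcomeCurve(
        patient_id="P1", disease=Disease.HCC, doses=grid,
        tcp_mean=np.full_like(grid, 0.95), tcp_sem=np.zeros_like(grid),
        ntcp_mean=np.linspace(0.01, 0.9, grid.size),
        ntcp_sem=np.zeros_like(grid),
    )
    recs = generate_ai_recommendations([curve], cfg)
    assert recs["P1"].dose == cfg.cohort.dose_min


def test_all_nonbelievers_never_adjust():
    cfg = dataclasses.replace(SimulationConfig.default(Disease.NSCLC, seed=9),
                              nonbeliever_fraction=1.0)
    study = generate_study(cfg)
    assert adjustment_frequency(study.records).count == 0
    assert not any(t.believer for t in study.truth)


def test_full_influence_no_noise_matches_ai_exactly():
    study = generate_study(SimulationConfig.idealized(Disease.NSCLC, 1.0, seed=10))
    for r in study.records:
        assert r.aia == pytest.approx(r.ai)
        assert agreement(r) == pytest.approx(0.0)


def test_half_influence_no_noise_gives_perfect_rank_correlation():
    study = generate_study(SimulationConfig.idealized(Disease.NSCLC, 0.5, seed=11))
    adj = [r.aia - r.un for r in study.records]
    dis = [r.ai - r.un for r in study.records]
    assert spearman(adj, dis).coefficient == pytest.approx(1.0)


def test_generated_trust_levels_consistent_with_answers():
    study = generate_study(SimulationConfig.default(Disease.HCC, seed=12))
    for r in study.records:
        assert trust_score(r.trust_answers) == r.trust_level
        assert 0 <= r.trust_level <= 5


def test_mixed_population_exercises_all_influence_classes():
    from collabrt.metrics import classify_influence

    cfg = dataclasses.replace(
        SimulationConfig.default(Disease.NSCLC, seed=13),
        cohort=dataclasses.replace(SimulationConfig.default("NSCLC").cohort,
                                   n_patients=30, n_evaluators=12),
        nonbeliever_fraction=0.25,
        rtoe_bypass_probability=0.8,
        un_soc_sd=0.3,
    )
    study = generate_study(cfg)
    classes = {classify_influence(r).value for r in study.records}
    assert classes == {
        "NO_INFLUENCE", "NOT_SURE", "ADJUSTED_WITH_AI", "ADJUSTED_VIA_RTOE"
    }


def test_influence_weight_recovery_by_regression():
    """Regressing enacted shifts on dissimilarity over believer records
    recovers the mean influence weight within 3 standard errors."""
    base = SimulationConfig.default(Disease.NSCLC, seed=21)
    cfg = dataclasses.replace(
        base,
        cohort=dataclasses.replace(base.cohort, n_patients=25, n_evaluators=10),
        nonbeliever_fraction=0.0,
        adjustment_deadband=0.0,
        rtoe_bypass_probability=0.0,
        dose_resolution=0.0,
        influence_weight_mean=0.6,
        influence_weight_sd=0.1,
    )
    study = generate_study(cfg)
    assert len(study.records) >= 200
    # Weights differ between evaluators, so aggregate per-evaluator slopes
    # (each estimates that evaluator's w) with their between-evaluator SE.
    slopes = []
    for ev in study.truth:
        recs = [r for r in study.records if r.evaluator_id == ev.evaluator_id]
        x = np.array([r.ai - r.un for r in recs])
        y = np.array([r.aia - r.un for r in recs])
        slopes.append(np.polyfit(x, y, 1)[0])
    slopes = np.array(slopes)
    se = slopes.std(ddof=1) / np.sqrt(slopes.size)
    assert abs(slopes.mean() - 0.6) <= 3 * se
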