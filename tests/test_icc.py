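import numpy as np
import pytest

from collabrt import (
    Disease,
    SimulationConfig,
    ValidationError,
    generate_study,
    icc_comparison,
    icc_two_way_random,
)
from collabrt.icc import decision_matrix

VARIANTS = [("C", "single"), ("A", "single"), ("C", "average"), ("A", "average")]


def oracle_icc(m, icc_type, unit):
    """Independent ANOVA decomposition via the classical computational
    sum-of-squares formulas (totals and squared totals, not means)."""
    m = np.asarray(m, float)
    n, k = m.shape
    g = m.sum()
    correction = g**2 / (n * k)
    ss_total = (m**2).sum() - correction
    ss_rows = (m.sum(axis=1) ** 2).sum() / k - correction
    ss_cols = (m.sum(axis=0) ** 2).sum() / n - correction
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if icc_type == "C" and unit == "single":
        return (msr - mse) / (msr + (k - 1) * mse)
    if icc_type == "A" and unit == "single":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc_type == "C" and unit == "average":
        return (msr - mse) / msr
    return (msr - mse) / (msr + (msc - mse) / n)


FIXED_4x3 = np.array(
    [[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0], [7.0, 1.0, 2.0]]
)


@pytest.mark.parametrize("icc_type, unit", VARIANTS)
def test_fixed_matrix_matches_sum_of_squares_oracle(icc_type, unit):
    res = icc_two_way_random(FIXED_4x3, icc_type, unit)
    assert res.value == pytest.approx(oracle_icc(FIXED_4x3, icc_type, unit), abs=1e-12)


def test_identical_columns_give_perfect_consistency():
    col = np.array([1.0, 3.0, 2.0, 5.0])
    m = np.column_stack([col, col, col])
    res = icc_two_way_random(m, "C", "single")
    assert res.value == 1.0
    assert res.degenerate


def test_constant_column_offsets_separate_consistency_from_agreement():
    col = np.array([1.0, 3.0, 2.0, 5.0])
    m = np.column_stack([col, col + 2.0, col - 1.0])
    assert icc_two_way_random(m, "C", "single").value == pytest.approx(1.0)
    assert icc_two_way_random(m, "A", "single").value < 1.0


@pytest.mark.parametrize("seed", range(4))
@pytest.mark.parametrize("icc_type", ["C", "A"])
def test_spearman_brown_identity(seed, icc_type):
    """ICC(.,k) = k*ICC(.,1) / (1 + (k-1)*ICC(.,1)) to machine precision."""
    rng = np.random.default_rng(seed)
    n, k = int(rng.integers(4, 9)), int(rng.integers(3, 10))
    m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
    single = icc_two_way_random(m, icc_type, "single").value
    average = icc_two_way_random(m, icc_type, "average").value
    assert average == pytest.approx(k * single / (1 + (k - 1) * single), abs=1e-12)


@pytest.mark.parametrize("icc_type, unit", VARIANTS)
def test_invariance_to_global_shift(icc_type, unit):
    rng = np.random.default_rng(5)
    m = rng.normal(size=(6, 4))
    base = icc_two_way_random(m, icc_type, unit)
    shifted = icc_two_way_random(m + 17.3, icc_type, unit)
    assert shifted.value == pytest.approx(base.value, abs=1e-10)
    assert shifted.ci_low == pytest.approx(base.ci_low, abs=1e-10)


def test_consistency_invariant_to_per_column_offsets():
    rng = np.random.default_rng(6)
    m = rng.normal(size=(6, 4))
    offsets = rng.normal(size=4) * 3
    base = icc_two_way_random(m, "C", "single").value
    assert icc_two_way_random(m + offsets, "C", "single").value == pytest.approx(
        base, abs=1e-10
    )


def test_agreement_not_above_consistency_when_raters_differ():
    """Systematic rater offsets penalize absolute agreement but not
    consistency (for a non-negative estimate, i.e. MSR >= MSE)."""
    rng = np.random.default_rng(7)
    m = (rng.normal(size=(8, 5))
         + 3 * rng.normal(size=(8, 1))            # patient signal
         + np.array([0.0, 1.0, -1.0, 2.0, 0.5]))  # rater offsets
    c = icc_two_way_random(m, "C", "single")
    a = icc_two_way_random(m, "A", "single")
    assert c.value >= 0  # construction guarantees row variance dominates
    assert a.value <= c.value + 1e-12


@pytest.mark.parametrize("icc_type, unit", VARIANTS)
def test_ci_contains_estimate_and_widens_with_confidence(icc_type, unit):
    rng = np.random.default_rng(8)
    m = rng.normal(size=(7, 5)) + 2 * rng.normal(size=(7, 1))
    r95 = icc_two_way_random(m, icc_type, unit, confidence=0.95)
    r99 = icc_two_way_random(m, icc_type, unit, confidence=0.99)
    assert r95.ci_low <= r95.value <= r95.ci_high
    assert r99.ci_low <= r95.ci_low and r99.ci_high >= r95.ci_high


def test_matches_pingouin_irr_equivalent():
    """Cross-check values and CIs against pingouin (which follows the R irr
    formulas) for all four two-way random variants; p-values compared for the
    consistency variants, where the reference uses the same residual df."""
    pg = pytest.importorskip("pingouin")
    import pandas as pd
    from pingouin import options as pg_options

    rng = np.random.default_rng(9)
    m = rng.normal(size=(8, 5)) + 1.5 * rng.normal(size=(8, 1))
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(8), 5),
            "rater": np.tile(np.arange(5), 8),
            "score": m.ravel(),
        }
    )
    saved = pg_options.copy()
    pg_options["round.column.CI95"] = None
    try:
        ref = pg.intraclass_corr(long, "target", "rater", "score").set_index("Type")
    finally:
        pg_options.update(saved)
    mapping = {
        ("A", "single"): "ICC(A,1)", ("C", "single"): "ICC(C,1)",
        ("A", "average"): "ICC(A,k)", ("C", "average"): "ICC(C,k)",
    }
    for (icc_type, unit), label in mapping.items():
        ours = icc_two_way_random(m, icc_type, unit)
        row = ref.loc[label]
        assert ours.value == pytest.approx(row["ICC"], abs=1e-10)
        assert ours.ci_low == pytest.approx(row["CI95"][0], abs=1e-8)
        assert ours.ci_high == pytest.approx(row["CI95"][1], abs=1e-8)
        if icc_type == "C":
            assert ours.p_value == pytest.approx(row["pval"], abs=1e-12)


def test_comparison_identical_phases_and_structure(make_record, nsclc):
    recs = []
    rng = np.random.default_rng(11)
    for i in range(4):
        for j in range(3):
            d = round(float(rng.uniform(1.6, 3.9)), 1)
            recs.append(
                make_record(patient_id=f"P{i}", evaluator_id=f"E{j}", un=d, aia=d)
            )
    table = icc_comparison(recs, nsclc)
    assert len(table) == 8
    un = table[table.phase == "unassisted"].set_index("variant")["value"]
    aia = table[table.phase == "ai_assisted"].set_index("variant")["value"]
    for v in un.index:
        assert aia[v] == pytest.approx(un[v])


def test_full_influence_collapses_assisted_matrix_to_ai(hcc):
    """w = 1 with no noise: every evaluator lands on the patient's AI dose,
    so the assisted columns are identical and every ICC variant is 1."""
    study = generate_study(SimulationConfig.idealized(Disease.HCC, 1.0, seed=4))
    table = icc_comparison(study.records, hcc)
    aia = table[table.phase == "ai_assisted"]
    assert (aia["value"] == 1.0).all()
    assert aia["degenerate"].all()


def test_incomplete_design_lists_missing_cells(make_record, nsclc):
    recs = [
        make_record(patient_id="P1", evaluator_id="E1"),
        make_record(patient_id="P1", evaluator_id="E2"),
        make_record(patient_id="P2", evaluator_id="E1"),
    ]
    with pytest.raises(ValidationError, match="P2.*E2"):
        decision_matrix(recs, "un")
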