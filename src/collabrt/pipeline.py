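"""End-to-end analysis orchestration.

`run_full_analysis` reproduces the quantitative surface of the study on any
validated record collection: derived metrics, adjustment frequencies
(overall / by evaluator / by patient), matched-pair randomization tests
grouped by evaluator and by patient, Pearson checks of un vs aia and the two
confidence levels, the Spearman correlation panel (each relationship for the
full cohort and for the subset excluding evaluators with zero decision
adjustments), the four-variant ICC comparison, the AI-influence truth-table
counts, and — when outcome curves are supplied — the outcome-change
classification and TCP(1-NTCP) score summary. Results are emitted as tidy
tables plus a structured JSON summary; never as figures.

Cohorts are analyzed strictly separately; nothing is pooled across diseases.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .icc import icc_comparison
from .metrics import adjustment_frequency, derive_table
from .outcomes import classify_outcome_changes, score_diff_summary
from .records import (
    AnalysisOptions,
    CohortConfig,
    DecisionRecord,
    OutcomeCurve,
    ValidationError,
)
from .stats import covariance_ellipse, paired_randomization_t, pearson, spearman

logger = logging.getLogger("collabrt")

#: The Spearman panel: (name, x column, y column) over the derived table.
SPEARMAN_PANELS: tuple[tuple[str, str, str], ...] = (
    ("adjustment_vs_dissimilarity", "dissimilarity", "adjustment_level"),
    ("trust_vs_agreement", "agreement", "trust_level"),
    ("aia_conf_vs_trust", "trust_level", "aia_conf"),
    ("delta_conf_vs_trust", "trust_level", "delta_conf"),
    ("delta_conf_vs_adjustment", "adjustment_level", "delta_conf"),
    ("un_conf_vs_closeness_un", "closeness_un", "un_conf"),
    ("aia_conf_vs_closeness_aia", "closeness_aia", "aia_conf"),
)


@dataclass
class AnalysisReport:
    disease: str
    n_records: int
    tables: dict[str, pd.DataFrame]
    meta: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-ready view: metadata plus every table as records."""
        return {
            "disease": self.disease,
            "n_records": self.n_records,
            "meta": self.meta,
            "tables": {
                name: df.to_dict(orient="records")
                for name, df in sorted(self.tables.items())
            },
        }


def subset_excluding_zero_adjusters(
    records: Sequence[DecisionRecord], tol: float
) -> list[DecisionRecord]:
    """Drop every record of evaluators who adjusted no decision at all."""
    by_eval: dict[str, list[DecisionRecord]] = {}
    for r in records:
        by_eval.setdefault(r.evaluator_id, []).append(r)
    keep = {
        ev
        for ev, recs in by_eval.items()
        if adjustment_frequency(recs, tol).count > 0
    }
    subset = [r for r in records if r.evaluator_id in keep]
    if not subset:
        logger.warning("every evaluator has zero adjustments; subset is empty")
    return subset


def _adjustment_tables(derived: pd.DataFrame) -> dict[str, pd.DataFrame]:
    def summarize(g: pd.DataFrame) -> pd.Series:
        count = int(g["adjustment_flag"].sum())
        return pd.Series(
            {"adjusted": count, "total": len(g),
             "percent": 100.0 * count / len(g)}
        )

    overall = summarize(derived).to_frame().T
    by_eval = (
        derived.groupby("evaluator_id", sort=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    by_patient = (
        derived.groupby("patient_id", sort=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    for df in (overall, by_eval, by_patient):
        df["adjusted"] = df["adjusted"].astype(int)
        df["total"] = df["total"].astype(int)
    return {
        "adjustment_overall": overall,
        "adjustment_by_evaluator": by_eval,
        "adjustment_by_patient": by_patient,
    }


def _randomization_table(
    derived: pd.DataFrame, group_col: str, options: AnalysisOptions
) -> pd.DataFrame:
    rows = []
    for gid, g in derived.groupby(group_col, sort=True):
        res = paired_randomization_t(
            g["un"].to_numpy(), g["aia"].to_numpy(),
            max_exact_n=options.max_exact_n,
            n_resamples=options.n_resamples,
            seed=options.seed,
        )
        rows.append(
            {
                group_col: gid,
                "n_pairs": res.n,
                "t_observed": res.t_observed,
                "p_value": res.p_value,
                "sig_code": res.sig_code,
                "method": res.method.value,
                "n_resamples": res.n_resamples,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def _correlation_panel(
    derived_full: pd.DataFrame,
    derived_subset: pd.DataFrame,
    confidence: float,
) -> pd.DataFrame:
    rows = []
    for subset_name, df in (
        ("all", derived_full),
        ("excluding_zero_adjusters", derived_subset),
    ):
        for name, xcol, ycol in SPEARMAN_PANELS:
            if len(df) < 3:
                rows.append({"panel": name, "subset": subset_name, "n": len(df),
                             "rho": np.nan, "p_value": np.nan, "sig_code": "N.S",
                             "degenerate": True})
                continue
            x = df[xcol].to_numpy(float)
            y = df[ycol].to_numpy(float)
            res = spearman(x, y)
            ell = covariance_ellipse(x, y, confidence)
            rows.append(
                {
                    "panel": name,
                    "subset": subset_name,
                    "x": xcol,
                    "y": ycol,
                    "n": res.n,
                    "rho": res.coefficient,
                    "p_value": res.p_value,
                    "sig_code": res.sig_code,
                    "degenerate": res.degenerate,
                    "ellipse_cx": ell.center[0],
                    "ellipse_cy": ell.center[1],
                    "ellipse_semi_major": ell.semi_major,
                    "ellipse_semi_minor": ell.semi_minor,
                    "ellipse_angle_rad": ell.orientation_rad,
                }
            )
    return pd.DataFrame(rows)


def _pearson_table(derived: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name, xcol, ycol in (
        ("un_vs_aia", "un", "aia"),
        ("un_conf_vs_aia_conf", "un_conf", "aia_conf"),
    ):
        res = pearson(derived[xcol].to_numpy(float), derived[ycol].to_numpy(float))
        rows.append(
            {
                "comparison": name,
                "n": res.n,
                "r": res.coefficient,
                "p_value": res.p_value,
                "sig_code": res.sig_code,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def _influence_tables(derived: pd.DataFrame) -> dict[str, pd.DataFrame]:
    counts = (
        derived["influence_class"].value_counts().rename_axis("influence_class")
        .reset_index(name="count").sort_values("influence_class", ignore_index=True)
    )
    by_eval = (
        derived.groupby("evaluator_id", sort=True)["influence_class"]
        .apply(lambda s: float((s == "NO_INFLUENCE").mean()))
        .reset_index(name="no_influence_fraction")
    )
    return {"influence_counts": counts, "influence_by_evaluator": by_eval}


def run_full_analysis(
    records: Sequence[DecisionRecord],
    cohort: CohortConfig,
    curves: Sequence[OutcomeCurve] | None = None,
    options: AnalysisOptions | None = None,
) -> AnalysisReport:
    """Compute every analysis stage; curves are required only for the
    outcome section, which is otherwise skipped with a recorded flag."""
    if not records:
        raise ValidationError("run_full_analysis needs at least one record")
    options = options or AnalysisOptions()
    tol = options.tolerance

    derived = derive_table(records, cohort, tol)
    subset_records = subset_excluding_zero_adjusters(records, tol)
    derived_subset = derive_table(subset_records, cohort, tol)

    tables: dict[str, pd.DataFrame] = {"derived": derived}
    tables.update(_adjustment_tables(derived))
    tables["randomization_by_evaluator"] = _randomization_table(
        derived, "evaluator_id", options
    )
    tables["randomization_by_patient"] = _randomization_table(
        derived, "patient_id", options
    )
    tables["pearson"] = _pearson_table(derived)
    tables["spearman_panel"] = _correlation_panel(
        derived, derived_subset, options.confidence
    )
    tables["icc"] = icc_comparison(records, cohort, options.confidence)
    tables.update(_influence_tables(derived))

    outcome_section = curves is not None
    if outcome_section:
        changes, counts = classify_outcome_changes(records, curves, tol)
        n_adj = sum(counts.values())
        tables["outcome_changes"] = pd.DataFrame(
            [
                {
                    "evaluator_id": c.evaluator_id,
                    "patient_id": c.patient_id,
                    "tcp_un": c.tcp_un,
                    "ntcp_un": c.ntcp_un,
                    "tcp_aia": c.tcp_aia,
                    "ntcp_aia": c.ntcp_aia,
                    "category": c.category.value,
                    "score_un": round(c.score_un, 4),
                    "score_aia": round(c.score_aia, 4),
                    "score_diff": round(c.score_diff, 4),
                }
                for c in changes
            ]
        )
        tables["outcome_categories"] = pd.DataFrame(
            [
                {"category": cat, "count": cnt,
                 "percent": 100.0 * cnt / n_adj if n_adj else np.nan}
                for cat, cnt in sorted(counts.items())
            ]
        )
        if changes:
            s = score_diff_summary(changes)
            tables["score_summary"] = pd.DataFrame(
                [
                    {
                        "n": s.n,
                        "mean": round(s.mean, 4),
                        "sd": round(s.sd, 4),
                        "median": round(s.median, 4),
                        "q1": round(s.q1, 4),
                        "q3": round(s.q3, 4),
                        "skew_direction": s.skew_direction,
                    }
                ]
            )

    meta = {
        "software": {"name": "collabrt", "version": __version__},
        "cohort": {
            "disease": cohort.disease.value,
            "dose_min": cohort.dose_min,
            "dose_max": cohort.dose_max,
            "soc_dose": cohort.soc_dose,
            "n_patients": cohort.n_patients,
            "n_evaluators": cohort.n_evaluators,
        },
        "options": dataclasses.asdict(options),
        "n_records": len(records),
        "subset_excluding_zero_adjusters": {
            "n_records": len(subset_records),
            "equals_full_cohort": len(subset_records) == len(records),
        },
        "outcome_section": outcome_section,
    }
    return AnalysisReport(
        disease=cohort.disease.value,
        n_records=len(records),
        tables=tables,
        meta=meta,
    )


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the structured JSON summary plus one tidy CSV per table.

    Output is bit-stable: identical report objects produce byte-identical
    files (no timestamps, sorted keys, default float repr).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    summary_path = out_dir / "report.json"
    summary_path.write_text(
        json.dumps(report.summary_dict(), indent=2, sort_keys=True,
                   allow_nan=True, default=_json_default)
        + "\n"
    )
    written.append(summary_path)
    for name, df in sorted(report.tables.items()):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    logger.info("wrote %d report files to %s", len(written), out_dir)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
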