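"""End-to-end study replication: simulate, process, calibrate, validate, agree.

`run_study` composes the whole pipeline on a synthetic cohort:

1. generate the cohort and split it into development / cross-validation,
2. extract steady-state summaries (final 2 min per activity),
3. fit the random-coefficients count->MET calibration on the development
   group and solve it at the 3 and 6 MET anchors (mixed-regression
   thresholds),
4. derive ROC-optimal thresholds on the development group,
5. cross-validate all four thresholds on the held-out group and select the
   per-intensity winner,
6. score minute-level posture agreement of both device rules against the
   observer record, and
7. compute the concurrent validity (Spearman) of the two devices' counts.

Everything is deterministic given the config (which carries the seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .agreement import AgreementTable, run_agreement
from .calibration import (
    CalibrationFit,
    IntensityAnchors,
    fit_random_coefficients,
    solve_threshold,
)
from .cohort import GeneratorConfig, ParticipantSession, generate_cohort
from .epochs import steady_state_table
from .roc import (
    SelectionResult,
    ThresholdEvaluation,
    evaluate_threshold,
    optimal_threshold,
    roc_curve,
    select_optimal,
)

__all__ = ["StudyReport", "spearman", "run_study", "report_to_dict"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyReport:
    calibration: CalibrationFit
    mr_thresholds: dict[str, float]  # intensity -> counts/15 s (exact)
    development_roc: dict[str, ThresholdEvaluation]
    development_auc: dict[str, float]
    cross_validation: SelectionResult
    agreement_ap: AgreementTable
    agreement_ag: AgreementTable
    concurrent_r: float
    concurrent_p: float
    steady_state: pd.DataFrame
    provenance: dict


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; (rho, p).

    The p-value uses the t approximation.  Constant input leaves ranks
    undefined and is an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_study(
    config: GeneratorConfig,
    anchors: IntensityAnchors = IntensityAnchors(),
    window_s: float = 120.0,
    granularity: str = "activity",
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Run the full calibration-and-validation study on one synthetic cohort.

    ``granularity`` selects the data points used for calibration and ROC:
    ``"activity"`` (default) uses per-activity steady-state means (five
    points per participant), ``"epoch"`` uses every epoch in the
    steady-state windows.
    """
    if granularity not in ("activity", "epoch"):
        raise ValueError("granularity must be 'activity' or 'epoch'")
    log.info("generating cohort: n=%d seed=%d", config.n_participants, config.seed)
    sessions = generate_cohort(config)
    ss = steady_state_table(sessions, window_s=window_s)

    points = _analysis_points(sessions, ss, granularity, window_s)
    dev = points[points["group"] == "development"]
    hold = points[points["group"] == "cross_validation"]

    log.info("fitting calibration on %d development points", len(dev))
    fit = fit_random_coefficients(dev[["participant_id", "counts", "met"]])

    mr_thresholds = {
        "MPA": solve_threshold(fit, anchors.moderate_met)[0],
        "VPA": solve_threshold(fit, anchors.vigorous_met)[0],
    }

    dev_roc: dict[str, ThresholdEvaluation] = {}
    dev_auc: dict[str, float] = {}
    for intensity, anchor in (("MPA", anchors.moderate_met), ("VPA", anchors.vigorous_met)):
        curve = roc_curve(dev["counts"], dev["met"] >= anchor)
        dev_roc[intensity] = optimal_threshold(curve, intensity=intensity)
        dev_auc[intensity] = curve.auc

    evaluations = []
    for intensity, anchor in (("MPA", anchors.moderate_met), ("VPA", anchors.vigorous_met)):
        labels = hold["met"] >= anchor
        evaluations.append(
            evaluate_threshold(
                mr_thresholds[intensity], hold["counts"], labels,
                method="mixed_regression", intensity=intensity,
            )
        )
        evaluations.append(
            evaluate_threshold(
                dev_roc[intensity].threshold, hold["counts"], labels,
                method="roc", intensity=intensity,
            )
        )
    selection = select_optimal(evaluations)

    agreement_ap, trace = run_agreement(sessions, "AP")
    agreement_ag, _ = run_agreement(sessions, "AG")

    r, p = spearman(ss["mean_ap"], ss["mean_ag"])

    provenance = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "granularity": granularity,
        "window_s": window_s,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    report = StudyReport(
        calibration=fit,
        mr_thresholds=mr_thresholds,
        development_roc=dev_roc,
        development_auc=dev_auc,
        cross_validation=selection,
        agreement_ap=agreement_ap,
        agreement_ag=agreement_ag,
        concurrent_r=r,
        concurrent_p=p,
        steady_state=ss,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(report, sessions, trace, config, Path(out_dir))
    return report


def _analysis_points(
    sessions: list[ParticipantSession],
    ss: pd.DataFrame,
    granularity: str,
    window_s: float,
) -> pd.DataFrame:
    """Calibration/ROC point set with columns participant_id, group, counts, met."""
    if granularity == "activity":
        return ss.rename(columns={"mean_ap": "counts"})[
            ["participant_id", "group", "counts", "met"]
        ].copy()
    rows = []
    for s in sessions:
        bouts: dict[str, list] = {}
        for e in s.epochs:
            bouts.setdefault(e.activity, []).append(e)
        for activity, epochs in bouts.items():
            if activity == "rest":
                continue
            end = epochs[-1].time_s + 15
            for e in epochs:
                if e.time_s >= end - window_s:
                    rows.append(
                        (s.participant_id, s.group, e.ap_counts, e.vo2 / s.resting_vo2)
                    )
    return pd.DataFrame(rows, columns=["participant_id", "group", "counts", "met"])


def report_to_dict(report: StudyReport) -> dict:
    """JSON-serializable view of a study report (steady-state table excluded)."""

    def ev(e: ThresholdEvaluation) -> dict:
        return {
            "method": e.method,
            "intensity": e.intensity,
            "threshold": e.threshold,
            "sensitivity_pct": e.sensitivity,
            "specificity_pct": e.specificity,
            "auc": e.auc,
        }

    def agr(t: AgreementTable) -> dict:
        return {
            "overall_agreement_pct": t.overall_agreement,
            "per_category": {
                c: {"sensitivity_pct": s, "predictive_value_pct": pv}
                for c, (s, pv) in t.per_category.items()
            },
            "confusion": t.confusion.to_dict(),
            "empty_prediction_categories": list(t.empty_prediction_categories),
        }

    fit = report.calibration
    return {
        "calibration": {
            "fixed_intercept": fit.fixed_intercept,
            "fixed_slope": fit.fixed_slope,
            "fixed_slope_se": fit.fixed_slope_se,
            "random_intercept_var": fit.random_intercept_var,
            "random_slope_var": fit.random_slope_var,
            "residual_var": fit.residual_var,
            "ccc": fit.ccc,
            "see": fit.see,
            "n_obs": fit.n_obs,
            "n_participants": fit.n_participants,
        },
        "mr_thresholds_counts_15s": report.mr_thresholds,
        "development_roc": {k: ev(v) for k, v in report.development_roc.items()},
        "development_auc": report.development_auc,
        "cross_validation": {
            "selected": {k: ev(v) for k, v in report.cross_validation.selected.items()},
            "trail": {
                k: [ev(e) for e in evs]
                for k, evs in report.cross_validation.trail.items()
            },
        },
        "agreement": {"AP": agr(report.agreement_ap), "AG": agr(report.agreement_ag)},
        "concurrent_validity": {
            "spearman_r": report.concurrent_r,
            "p_value": report.concurrent_p,
        },
        "provenance": report.provenance,
    }


def _write_outputs(report, sessions, trace, config, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    mio.write_cohort_files(sessions, out_dir, config=config)
    report.steady_state.to_csv(out_dir / "steady_state.csv", index=False)
    trace.to_csv(out_dir / "minute_trace.csv", index=False)
    d = report_to_dict(report)
    (out_dir / "report.json").write_text(json.dumps(d, indent=2))
    (out_dir / "calibration.json").write_text(
        json.dumps(
            {**d["calibration"], "thresholds_counts_15s": d["mr_thresholds_counts_15s"]},
            indent=2,
        )
    )
    (out_dir / "thresholds.json").write_text(json.dumps(d["cross_validation"], indent=2))
    (out_dir / "agreement.json").write_text(json.dumps(d["agreement"], indent=2))
    log.info("study outputs written to %s", out_dir)
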