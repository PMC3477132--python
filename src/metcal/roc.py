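"""ROC threshold derivation, cross-validation and threshold selection.

Candidate count thresholds are the midpoints between consecutive distinct
observed scores, plus one sentinel below the minimum and one above the
maximum, so that the classification rule ``score >= threshold -> positive``
is symmetric around every observed value.  AUC is the trapezoidal area over
(1 - specificity, sensitivity), which equals the probability that a random
positive outscores a random negative (ties counted half).

Cross-validation evaluates externally supplied thresholds (e.g. from the
mixed-regression calibration and from development-group ROC) on a held-out
group; per intensity the winner is the candidate with the highest AUC, AUC
ties (at reporting precision) broken by the larger sensitivity+specificity
sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RocCurve",
    "ThresholdEvaluation",
    "roc_curve",
    "optimal_threshold",
    "evaluate_threshold",
    "select_optimal",
]

_AUC_TIE_DECIMALS = 2  # AUCs are compared at reporting precision


@dataclass(frozen=True)
class RocCurve:
    """Full ROC over candidate thresholds (ascending)."""

    candidate_thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_rule: str = "MET >= anchor"

    def __post_init__(self) -> None:
        n = len(self.candidate_thresholds)
        if len(self.sensitivity) != n or len(self.specificity) != n:
            raise ValueError("curve arrays must have equal length")


@dataclass(frozen=True)
class ThresholdEvaluation:
    """One threshold's held-out (or in-sample) operating point."""

    method: str  # "mixed_regression" | "roc"
    intensity: str  # "MPA" | "VPA"
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    if s.shape != y.shape or s.ndim != 1 or len(s) == 0:
        raise ValueError("scores and labels must be equal-length vectors")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def roc_curve(scores, labels, positive_rule: str = "MET >= anchor") -> RocCurve:
    """Build the ROC curve of ``score >= threshold`` against boolean labels."""
    s, y = _validate(scores, labels)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])

    pos = s[y]
    neg = s[~y]
    sens = np.array([(pos >= t).mean() for t in cands])
    spec = np.array([(neg < t).mean() for t in cands])

    fpr = 1.0 - spec  # descending as thresholds ascend
    auc = float(-np.trapezoid(sens, fpr))
    return RocCurve(cands, sens, spec, auc, positive_rule)


def optimal_threshold(curve: RocCurve, intensity: str = "MPA") -> ThresholdEvaluation:
    """Candidate maximizing sensitivity + specificity.

    Ties broken by higher sensitivity, then by lower threshold.
    """
    j = curve.sensitivity + curve.specificity
    best = None
    for i in range(len(curve.candidate_thresholds)):
        key = (j[i], curve.sensitivity[i], -curve.candidate_thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return ThresholdEvaluation(
        method="roc",
        intensity=intensity,
        threshold=float(curve.candidate_thresholds[i]),
        sensitivity=float(100.0 * curve.sensitivity[i]),
        specificity=float(100.0 * curve.specificity[i]),
        auc=curve.auc,
    )


def evaluate_threshold(
    threshold: float,
    scores,
    labels,
    method: str = "mixed_regression",
    intensity: str = "MPA",
) -> ThresholdEvaluation:
    """Sensitivity/specificity of one threshold, with the data's full-curve AUC.

    Sensitivity is the percentage of positives at or above the threshold;
    specificity the percentage of negatives below it.  The attached AUC is a
    property of the score/label data, not of the threshold, so candidate
    thresholds evaluated on the same holdout share it (and selection then
    falls through to the sensitivity+specificity sum).
    """
    s, y = _validate(scores, labels)
    sens = 100.0 * float((s[y] >= threshold).mean())
    spec = 100.0 * float((s[~y] < threshold).mean())
    return ThresholdEvaluation(
        method=method,
        intensity=intensity,
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        auc=roc_curve(s, y).auc,
    )


@dataclass(frozen=True)
class SelectionResult:
    """Per-intensity winner plus the ranked decision trail."""

    selected: dict[str, ThresholdEvaluation]
    trail: dict[str, list[ThresholdEvaluation]] = field(default_factory=dict)


def select_optimal(evaluations: list[ThresholdEvaluation]) -> SelectionResult:
    """Pick the best threshold per intensity.

    Ranking: highest AUC first; where AUCs tie at reporting precision, the
    larger sensitivity + specificity sum wins.
    """
    if not evaluations:
        raise ValueError("no evaluations to select from")
    by_intensity: dict[str, list[ThresholdEvaluation]] = {}
    for ev in evaluations:
        by_intensity.setdefault(ev.intensity, []).append(ev)

    selected = {}
    trail = {}
    for intensity, evs in by_intensity.items():
        ranked = sorted(
            evs,
            key=lambda e: (
                round(e.auc, _AUC_TIE_DECIMALS),
                e.sensitivity + e.specificity,
            ),
            reverse=True,
        )
        trail[intensity] = ranked
        selected[intensity] = ranked[0]
    return SelectionResult(selected=selected, trail=trail)
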