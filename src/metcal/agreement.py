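"""Minute-by-minute posture agreement against direct observation.

Two device rules are compared with the observer's record over the sitting,
standing and slow-walking portions of the protocol:

* the thigh monitor's inclinometer labels (sitting/lying, standing,
  stepping), and
* the hip accelerometer's count rule, which calls a minute sedentary
  (sitting/lying) when it accumulates fewer than 100 counts and stepping
  otherwise — a rule that is structurally unable to emit "standing".

Agreement is summarized by overall percentage agreement (trace over total of
the 3x3 confusion matrix), per-category sensitivity (row-normalized) and
per-category predictive value (column-normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import POSTURES, SITTING_LYING, STEPPING, ParticipantSession
from .epochs import epochs_to_minutes

__all__ = [
    "AgreementTable",
    "ag_sedentary_classify",
    "agreement_stats",
    "run_agreement",
    "AGREEMENT_ACTIVITIES",
]

AG_SEDENTARY_CPM = 100.0
AGREEMENT_ACTIVITIES = ("sit", "stand", "slow_walk")


@dataclass(frozen=True)
class AgreementTable:
    """Confusion-derived agreement summary (percent scale)."""

    overall_agreement: float
    per_category: dict[str, tuple[float, float]]  # category -> (sens %, PV %)
    confusion: pd.DataFrame  # observed rows x predicted columns
    empty_prediction_categories: tuple[str, ...] = field(default_factory=tuple)

    def sensitivity(self, category: str) -> float:
        return self.per_category[category][0]

    def predictive_value(self, category: str) -> float:
        return self.per_category[category][1]


def ag_sedentary_classify(counts_per_min: float) -> str:
    """Posture category implied by the <100 counts/min sedentary rule.

    Below the cut the minute is called sitting/lying; at or above it,
    stepping.  Standing cannot be expressed by a count rule.
    """
    if counts_per_min < 0:
        raise ValueError("counts must be non-negative")
    return SITTING_LYING if counts_per_min < AG_SEDENTARY_CPM else STEPPING


def agreement_stats(observed, predicted) -> AgreementTable:
    """Percentage agreement, sensitivity and predictive value per category.

    ``overall = 100 * correct / total``;
    ``sensitivity(c) = 100 * correct_in_c / observed_in_c``;
    ``predictive_value(c) = 100 * correct_in_c / predicted_in_c`` (0 with a
    flag when the device never predicts ``c``).
    """
    obs = list(observed)
    pred = list(predicted)
    if len(obs) != len(pred) or not obs:
        raise ValueError("observed and predicted must be equal nonzero length")
    for lab in set(obs) | set(pred):
        if lab not in POSTURES:
            raise ValueError(f"unknown posture category {lab!r}")

    cats = list(POSTURES)
    conf = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for o, p in zip(obs, pred):
        conf.loc[o, p] += 1

    total = conf.to_numpy().sum()
    overall = 100.0 * np.trace(conf.to_numpy()) / total

    per_category = {}
    empty = []
    for c in cats:
        row = conf.loc[c].sum()
        col = conf[c].sum()
        correct = conf.loc[c, c]
        sens = 100.0 * correct / row if row else 0.0
        if col:
            pv = 100.0 * correct / col
        else:
            pv = 0.0
            if row:  # observed but never predicted: 0/0 reported as 0 with flag
                empty.append(c)
        per_category[c] = (float(sens), float(pv))

    # algebraic identity: overall equals the observed-weighted sensitivity mean
    weighted = sum(
        per_category[c][0] * conf.loc[c].sum() for c in cats if conf.loc[c].sum()
    ) / total
    assert abs(weighted - overall) < 1e-9

    return AgreementTable(
        overall_agreement=float(overall),
        per_category=per_category,
        confusion=conf,
        empty_prediction_categories=tuple(empty),
    )


def run_agreement(
    sessions: list[ParticipantSession], device: str
) -> tuple[AgreementTable, pd.DataFrame]:
    """Minute-level agreement for a cohort, restricted to the comparison set.

    Minutes are built from each session's epoch stream and filtered to the
    sitting, standing and slow-walk bouts (the activities over which the
    sedentary rule is meaningfully contested).  ``device`` selects the
    prediction stream: ``"AP"`` uses the inclinometer labels, ``"AG"`` the
    <100 counts/min rule on summed minute counts.

    Returns the :class:`AgreementTable` and a per-minute trace
    (``participant_id, minute, observed, ap_pred, ag_counts, ag_pred``).
    """
    if device not in ("AP", "AG"):
        raise ValueError("device must be 'AP' or 'AG'")
    rows = []
    for s in sessions:
        if not s.observation_log:
            raise ValueError(f"{s.participant_id}: missing observation log")
        minutes = epochs_to_minutes(list(s.epochs))
        minutes = minutes[minutes["activity"].isin(AGREEMENT_ACTIVITIES)]
        for r in minutes.itertuples():
            rows.append(
                (
                    s.participant_id,
                    int(r.minute_start // 60),
                    r.posture_truth,
                    r.ap_posture,
                    float(r.ag_counts_per_min),
                    ag_sedentary_classify(r.ag_counts_per_min),
                )
            )
    trace = pd.DataFrame(
        rows,
        columns=["participant_id", "minute", "observed", "ap_pred", "ag_counts", "ag_pred"],
    )
    predicted = trace["ap_pred"] if device == "AP" else trace["ag_pred"]
    table = agreement_stats(trace["observed"], predicted)
    return table, trace
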