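"""Epoch-level processing: synchronization, steady state, MET scoring.

Implements the data-processing conventions of a laboratory calibration
protocol: breath-level VO2 is averaged into 15 s epochs aligned with the
device clocks, each non-rest activity is summarized over the final two
minutes of its bout (the steady-state window), MET scores are individualized
as activity VO2 divided by the participant's resting VO2, and epochs are
aggregated into minutes for count-per-minute posture rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EPOCH_S, EpochRecord, ParticipantSession

__all__ = [
    "SteadyStateSummary",
    "resample_to_epochs",
    "extract_steady_state",
    "met_score",
    "resting_vo2_from_rest_bout",
    "epochs_to_minutes",
    "steady_state_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SteadyStateSummary:
    """Final-window means for one participant-activity bout."""

    participant_id: str
    group: str
    activity: str
    mean_vo2: float
    mean_ap_counts: float
    mean_ag_counts: float
    met: float
    n_epochs: int


def resample_to_epochs(
    samples: list[tuple[float, float]], epoch_s: float = EPOCH_S
) -> list[tuple[float, float]]:
    """Average time-stamped samples into fixed epochs.

    Parameters
    ----------
    samples
        Time-sorted ``(time_s, value)`` pairs (e.g. breath-by-breath VO2).
    epoch_s
        Epoch length in seconds; epochs are half-open ``[t, t + epoch_s)``
        aligned at time 0.

    Returns one ``(epoch_start, mean)`` per epoch that contains at least one
    sample; empty epochs inside the covered range are omitted with a warning.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    if not samples:
        raise ValueError("no samples to resample")
    times = np.asarray([t for t, _ in samples], dtype=float)
    values = np.asarray([v for _, v in samples], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("samples must be time-sorted")

    bins = np.floor(times / epoch_s).astype(int)
    out = []
    for b in range(bins.min(), bins.max() + 1):
        mask = bins == b
        if not mask.any():
            log.warning("epoch starting at %s s has no samples; omitted", b * epoch_s)
            continue
        out.append((b * epoch_s, float(values[mask].mean())))
    return out


def met_score(activity_vo2: float, resting_vo2: float) -> float:
    """Individualized MET: activity VO2 over resting VO2 (both mL/kg/min)."""
    if activity_vo2 <= 0 or resting_vo2 <= 0:
        raise ValueError("VO2 inputs must be positive")
    return activity_vo2 / resting_vo2


def resting_vo2_from_rest_bout(
    session: ParticipantSession, window_s: float = 300.0
) -> float:
    """Resting VO2 as the mean over the final ``window_s`` of the rest bout.

    The rest bout is long (25 min) precisely so the participant settles; the
    final five minutes are the most settled portion and define the resting
    metabolic rate used as the MET denominator.
    """
    rest = [e for e in session.epochs if e.activity == "rest"]
    if not rest:
        raise ValueError(f"{session.participant_id}: no rest bout")
    end = rest[-1].time_s + EPOCH_S
    tail = [e.vo2 for e in rest if e.time_s >= end - window_s]
    if not tail:
        raise ValueError(f"{session.participant_id}: rest bout shorter than window")
    return float(np.mean(tail))


def extract_steady_state(
    session: ParticipantSession,
    window_s: float = 120.0,
    resting_vo2: float | None = None,
) -> list[SteadyStateSummary]:
    """Summarize each non-rest activity over the final ``window_s`` of its bout.

    Rest is excluded from the summaries (it supplies the MET denominator
    only).  A bout shorter than the window is an error naming the bout.
    """
    if resting_vo2 is None:
        resting_vo2 = session.resting_vo2
    if resting_vo2 <= 0:
        raise ValueError("resting VO2 must be positive")

    summaries = []
    for activity, bout in _iter_bouts(session.epochs):
        if activity == "rest":
            continue
        bout_end = bout[-1].time_s + EPOCH_S
        duration = bout_end - bout[0].time_s
        if duration < window_s:
            raise ValueError(
                f"{session.participant_id}: {activity} bout ({duration:.0f} s) "
                f"shorter than steady-state window ({window_s:.0f} s)"
            )
        window = [e for e in bout if e.time_s >= bout_end - window_s]
        mean_vo2 = float(np.mean([e.vo2 for e in window]))
        summaries.append(
            SteadyStateSummary(
                participant_id=session.participant_id,
                group=session.group,
                activity=activity,
                mean_vo2=mean_vo2,
                mean_ap_counts=float(np.mean([e.ap_counts for e in window])),
                mean_ag_counts=float(np.mean([e.ag_counts for e in window])),
                met=met_score(mean_vo2, resting_vo2),
                n_epochs=len(window),
            )
        )
    return summaries


def steady_state_table(
    sessions: list[ParticipantSession], window_s: float = 120.0
) -> pd.DataFrame:
    """Steady-state summaries for a whole cohort as a tidy DataFrame."""
    rows = [
        s
        for session in sessions
        for s in extract_steady_state(session, window_s=window_s)
    ]
    return pd.DataFrame(
        [
            (
                s.participant_id,
                s.group,
                s.activity,
                s.mean_vo2,
                s.mean_ap_counts,
                s.mean_ag_counts,
                s.met,
                s.n_epochs,
            )
            for s in rows
        ],
        columns=[
            "participant_id",
            "group",
            "activity",
            "mean_vo2",
            "mean_ap",
            "mean_ag",
            "met",
            "n_epochs",
        ],
    )


def _iter_bouts(epochs: tuple[EpochRecord, ...]):
    """Yield (activity, contiguous epoch run) in stream order."""
    bout: list[EpochRecord] = []
    for e in epochs:
        if bout and e.activity != bout[-1].activity:
            yield bout[-1].activity, bout
            bout = []
        bout.append(e)
    if bout:
        yield bout[-1].activity, bout


def epochs_to_minutes(epochs: list[EpochRecord]) -> pd.DataFrame:
    """Aggregate 15 s epochs into non-overlapping 60 s minutes.

    Counts are summed over the four member epochs; postures (observed truth
    and device label) are assigned by majority, ties broken toward the label
    of the earliest epoch in the minute.  Minutes are aligned to the protocol
    start; a partial trailing minute is dropped.  A gap in the epoch stream
    is an error.

    Returns a DataFrame with columns ``minute_start, activity,
    ag_counts_per_min, ap_counts_per_min, posture_truth, ap_posture``.
    """
    if not epochs:
        raise ValueError("no epochs")
    times = [e.time_s for e in epochs]
    if any(b - a != EPOCH_S for a, b in zip(times, times[1:])):
        raise ValueError("gap or irregular spacing in epoch stream")

    per_min = 60 // EPOCH_S
    rows = []
    for i in range(0, len(epochs) - (len(epochs) % per_min), per_min):
        chunk = epochs[i : i + per_min]
        if chunk[0].time_s % 60 != 0:
            # alignment to protocol start: only whole minutes from t=0
            raise ValueError("epoch stream does not start on a minute boundary")
        rows.append(
            (
                chunk[0].time_s,
                _majority([e.activity for e in chunk]),
                sum(e.ag_counts for e in chunk),
                sum(e.ap_counts for e in chunk),
                _majority([e.posture_truth for e in chunk]),
                _majority([e.ap_posture for e in chunk]),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "minute_start",
            "activity",
            "ag_counts_per_min",
            "ap_counts_per_min",
            "posture_truth",
            "ap_posture",
        ],
    )


def _majority(labels: list[str]) -> str:
    counts: dict[str, int] = {}
    for lab in labels:  # first-seen order breaks ties toward earlier epochs
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    for lab in labels:
        if counts[lab] == best:
            return lab
    raise AssertionError("unreachable")
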