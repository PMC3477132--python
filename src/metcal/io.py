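"""Delimited-text serialization for cohorts, configs and stage outputs.

File dialects
-------------
``epochs.csv``
    ``participant_id,group,time_s,activity,ap_counts,ag_counts,vo2,ap_posture,posture_truth``
``observations.csv``
    ``participant_id,start_s,end_s,posture_truth``
``resting.csv``
    ``participant_id,resting_vo2`` (the per-participant MET denominator)
``cohort.yaml``
    a serialized :class:`~metcal.cohort.GeneratorConfig`
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (
    ActivityProfile,
    EpochRecord,
    GeneratorConfig,
    ParticipantSession,
)

__all__ = [
    "write_session_files",
    "write_cohort_files",
    "read_cohort_files",
    "sessions_to_frame",
    "write_config",
    "read_config",
]

EPOCH_COLUMNS = [
    "participant_id",
    "group",
    "time_s",
    "activity",
    "ap_counts",
    "ag_counts",
    "vo2",
    "ap_posture",
    "posture_truth",
]


def sessions_to_frame(sessions: list[ParticipantSession]) -> pd.DataFrame:
    """Flatten sessions into one epoch-per-row DataFrame."""
    rows = []
    for s in sessions:
        for e in s.epochs:
            rows.append(
                (
                    s.participant_id,
                    s.group,
                    e.time_s,
                    e.activity,
                    e.ap_counts,
                    e.ag_counts,
                    e.vo2,
                    e.ap_posture,
                    e.posture_truth,
                )
            )
    return pd.DataFrame(rows, columns=EPOCH_COLUMNS)


def write_session_files(session: ParticipantSession, directory: str | Path) -> dict[str, Path]:
    """Write one participant's files; see module docstring for dialects."""
    return write_cohort_files([session], directory)


def write_cohort_files(
    sessions: list[ParticipantSession],
    directory: str | Path,
    config: GeneratorConfig | None = None,
) -> dict[str, Path]:
    """Write ``epochs.csv``, ``observations.csv``, ``resting.csv`` (and
    optionally ``cohort.yaml``) for a list of sessions.

    Raises ``ValueError`` on an empty cohort or a session with no epochs.
    """
    if not sessions:
        raise ValueError("no sessions to write")
    for s in sessions:
        if not s.epochs:
            raise ValueError(f"session {s.participant_id} has no epochs")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    paths = {
        "epochs": directory / "epochs.csv",
        "observations": directory / "observations.csv",
        "resting": directory / "resting.csv",
    }
    # %.17g guarantees float64 round-trip through text
    sessions_to_frame(sessions).to_csv(paths["epochs"], index=False, float_format="%.17g")

    obs_rows = [
        (s.participant_id, start, end, posture)
        for s in sessions
        for (start, end, posture) in s.observation_log
    ]
    pd.DataFrame(
        obs_rows, columns=["participant_id", "start_s", "end_s", "posture_truth"]
    ).to_csv(paths["observations"], index=False)

    pd.DataFrame(
        [(s.participant_id, s.resting_vo2) for s in sessions],
        columns=["participant_id", "resting_vo2"],
    ).to_csv(paths["resting"], index=False, float_format="%.17g")

    if config is not None:
        paths["config"] = directory / "cohort.yaml"
        write_config(config, paths["config"])
    return paths


def read_cohort_files(directory: str | Path) -> list[ParticipantSession]:
    """Inverse of :func:`write_cohort_files`; preserves participant order."""
    directory = Path(directory)
    epochs = pd.read_csv(directory / "epochs.csv", float_precision="round_trip")
    observations = pd.read_csv(directory / "observations.csv")
    resting = pd.read_csv(
        directory / "resting.csv", float_precision="round_trip"
    ).set_index("participant_id")

    sessions = []
    for pid, sub in epochs.groupby("participant_id", sort=False):
        sub = sub.sort_values("time_s")
        recs = tuple(
            EpochRecord(
                time_s=int(r.time_s),
                activity=r.activity,
                ap_counts=float(r.ap_counts),
                ag_counts=float(r.ag_counts),
                vo2=float(r.vo2),
                ap_posture=r.ap_posture,
                posture_truth=r.posture_truth,
            )
            for r in sub.itertuples()
        )
        obs = observations[observations["participant_id"] == pid]
        log = tuple(
            (int(r.start_s), int(r.end_s), r.posture_truth) for r in obs.itertuples()
        )
        sessions.append(
            ParticipantSession(
                participant_id=pid,
                group=sub["group"].iloc[0],
                resting_vo2=float(resting.loc[pid, "resting_vo2"]),
                epochs=recs,
                observation_log=log,
            )
        )
    return sessions


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["profiles"] = [dataclasses.asdict(p) for p in config.profiles]
    data["resting_vo2_range"] = list(config.resting_vo2_range)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path: str | Path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text())
    profiles = tuple(ActivityProfile(**p) for p in data.pop("profiles"))
    data["resting_vo2_range"] = tuple(data["resting_vo2_range"])
    return GeneratorConfig(profiles=profiles, **data)
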