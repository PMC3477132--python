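"""Synthetic calibration cohorts for activity-monitor cut-point studies.

This module generates laboratory-style calibration sessions: each simulated
participant completes a fixed protocol (rest lying, sitting, standing, slow
walk, brisk walk, light jog) while "wearing" a thigh-mounted monitor (AP),
a hip-mounted accelerometer (AG) and an indirect calorimeter.  Epoch-level
activity counts, oxygen uptake and posture labels are drawn from
activity-specific distributions so that every downstream analysis stage
(steady-state extraction, mixed-model calibration, ROC thresholding,
posture-agreement scoring) can be exercised without any real device data.

The default parameterization reproduces the published development-group
summary statistics of an adolescent-female protocol: per-activity count and
MET means/SDs, 15 s epochs, a 15/15 development/cross-validation split, and
a participant-varying linear count->MET relation whose fixed line passes
through 3 METs at 2997 counts/15 s and 6 METs at 7428 counts/15 s.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIVITIES",
    "POSTURES",
    "SITTING_LYING",
    "STANDING",
    "STEPPING",
    "ActivityProfile",
    "GeneratorConfig",
    "EpochRecord",
    "ParticipantSession",
    "CohortConfigError",
    "default_config",
    "generate_cohort",
]

EPOCH_S = 15

SITTING_LYING = "sitting_lying"
STANDING = "standing"
STEPPING = "stepping"
POSTURES = (SITTING_LYING, STANDING, STEPPING)

ACTIVITIES = ("rest", "sit", "stand", "slow_walk", "brisk_walk", "jog")

# Fixed count->MET line anchored at (2997 counts/15s, 3 MET) and
# (7428 counts/15s, 6 MET).
DEFAULT_SLOPE = 3.0 / (7428.0 - 2997.0)
DEFAULT_INTERCEPT = 3.0 - DEFAULT_SLOPE * 2997.0


class CohortConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class ActivityProfile:
    """Per-activity sampling parameters.

    Count parameters are in device counts per 15 s epoch; MET parameters are
    multiples of resting oxygen uptake.  ``posture_truth`` is the posture a
    direct observer would record throughout a bout of this activity.
    """

    label: str
    duration_min: float
    ap_count_mean: float
    ap_count_sd: float
    ag_count_mean: float
    ag_count_sd: float
    met_mean: float
    met_sd: float
    posture_truth: str

    def __post_init__(self) -> None:
        if self.label not in ACTIVITIES:
            raise CohortConfigError(f"unknown activity label {self.label!r}")
        if self.duration_min <= 0:
            raise CohortConfigError(f"{self.label}: duration must be positive")
        for name in ("ap_count_sd", "ag_count_sd", "met_sd"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{self.label}: {name} must be >= 0")
        for name in ("ap_count_mean", "ag_count_mean"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{self.label}: {name} must be >= 0")
        if self.posture_truth not in POSTURES:
            raise CohortConfigError(
                f"{self.label}: unknown posture {self.posture_truth!r}"
            )

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_min * 60 / EPOCH_S))


def _default_profiles() -> tuple[ActivityProfile, ...]:
    # Development-group per-activity summaries: AP/AG counts per 15 s and MET
    # scores, mean (SD).  Rest: 25 min lying, counts zero, 1 MET by definition
    # of the resting denominator (small within-session fluctuation).
    return (
        ActivityProfile("rest", 25.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.05, SITTING_LYING),
        ActivityProfile("sit", 5.0, 5.0, 8.0, 0.0, 1.0, 1.1, 0.2, SITTING_LYING),
        ActivityProfile("stand", 5.0, 15.0, 22.0, 1.0, 2.0, 1.1, 0.2, STANDING),
        ActivityProfile("slow_walk", 7.0, 3098.0, 858.0, 632.0, 174.0, 3.0, 0.7, STEPPING),
        ActivityProfile("brisk_walk", 7.0, 5011.0, 869.0, 940.0, 156.0, 3.9, 0.8, STEPPING),
        ActivityProfile("jog", 7.0, 11086.0, 1624.0, 2368.0, 406.0, 8.5, 1.9, STEPPING),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Attributes
    ----------
    n_participants, n_development
        Cohort size and size of the equation-development group; the remainder
        forms the cross-validation group.
    profiles
        One :class:`ActivityProfile` per protocol activity, in protocol order.
    count_met_slope, count_met_intercept
        Fixed population count->MET line (MET per count/15 s, MET).
    count_met_correlation
        Target within-activity correlation between AP counts and MET, in
        [0, 1].  Attained by giving the MET residual a count-correlated
        component; where the count-mediated correlation already exceeds the
        target it is left as-is.
    residual_met_sd
        Total SD of the epoch-level MET residual around the participant line.
    participant_intercept_sd, participant_slope_sd
        SDs of the participant-level random intercept (MET) and random slope
        (MET per count/15 s).
    ap_ag_correlation
        Within-activity correlation between AP and AG epoch counts, in [0, 1].
    posture_transition_latency
        Number of epochs after each bout boundary during which the simulated
        inclinometer still reports the previous bout's posture.
    resting_vo2_range
        Uniform range (mL/kg/min) for per-participant resting oxygen uptake.
    met_floor
        Lower clamp on simulated MET values (keeps VO2 positive).
    seed
        Seed for all randomness; identical configs generate identical cohorts.
    """

    n_participants: int = 30
    n_development: int = 15
    profiles: tuple[ActivityProfile, ...] = field(default_factory=_default_profiles)
    count_met_slope: float = DEFAULT_SLOPE
    count_met_intercept: float = DEFAULT_INTERCEPT
    count_met_correlation: float = 0.7
    residual_met_sd: float = 1.13
    participant_intercept_sd: float = 0.15
    participant_slope_sd: float = 0.1 * DEFAULT_SLOPE
    ap_ag_correlation: float = 0.8
    posture_transition_latency: int = 1
    resting_vo2_range: tuple[float, float] = (3.4, 4.2)
    met_floor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise CohortConfigError("need at least 2 participants")
        if not 0 < self.n_development < self.n_participants:
            raise CohortConfigError("n_development must be in (0, n_participants)")
        if not 0.0 <= self.count_met_correlation <= 1.0:
            raise CohortConfigError("count_met_correlation must lie in [0, 1]")
        if not 0.0 <= self.ap_ag_correlation <= 1.0:
            raise CohortConfigError("ap_ag_correlation must lie in [0, 1]")
        if self.posture_transition_latency < 0:
            raise CohortConfigError("posture_transition_latency must be >= 0")
        if self.residual_met_sd < 0:
            raise CohortConfigError("residual_met_sd must be >= 0")
        if min(self.participant_intercept_sd, self.participant_slope_sd) < 0:
            raise CohortConfigError("random-effect SDs must be >= 0")
        lo, hi = self.resting_vo2_range
        if not 0 < lo <= hi:
            raise CohortConfigError("resting_vo2_range must be positive and ordered")
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise CohortConfigError("duplicate activity profiles")

    def profile(self, label: str) -> ActivityProfile:
        for p in self.profiles:
            if p.label == label:
                return p
        raise KeyError(label)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class EpochRecord:
    """One 15 s epoch of synchronized device and calorimetry data."""

    time_s: int
    activity: str
    ap_counts: float
    ag_counts: float
    vo2: float
    ap_posture: str
    posture_truth: str


@dataclass(frozen=True)
class ParticipantSession:
    """A participant's full synchronized protocol stream.

    ``observation_log`` holds the direct-observer record: one
    ``(start_s, end_s, posture_truth)`` interval per non-rest bout.
    """

    participant_id: str
    group: str
    resting_vo2: float
    epochs: tuple[EpochRecord, ...]
    observation_log: tuple[tuple[int, int, str], ...]


def default_config(seed: int = 0) -> GeneratorConfig:
    """Return the study-default configuration (30 participants, 15/15 split)."""
    return GeneratorConfig(seed=seed)


def _residual_count_weight(u: float, rho: float) -> float:
    """Weight of the count z-score inside the MET residual.

    With MET = line(counts) + s*(w*z_c + sqrt(1-w^2)*z_i) and u = b*sigma_c/s,
    corr(counts, MET) = (u+w)/sqrt((u+w)^2 + 1-w^2).  Solving for the target
    correlation ``rho`` gives a quadratic in w; when the count-mediated
    correlation already exceeds rho (discriminant < 0) the target is
    unattainable without distorting the slope, and w = 0 is used.
    """
    if rho <= 0.0 or u < 0:
        return 0.0
    disc = 1.0 - u * u * (1.0 - rho * rho)
    if disc <= 0.0:
        return 0.0
    w = -u * (1.0 - rho * rho) + rho * math.sqrt(disc)
    return float(np.clip(w, -1.0, 1.0))


def generate_cohort(config: GeneratorConfig) -> list[ParticipantSession]:
    """Generate one synthetic session per participant.

    Within each activity bout, AP counts are Gaussian with the profile's
    mean/SD, clipped at zero; AG counts share a bivariate-normal z-score with
    the AP draw at the configured correlation.  Non-rest MET values follow the
    participant's random-coefficients line applied to the AP counts plus a
    residual whose total SD is ``residual_met_sd`` and whose count-correlated
    share targets ``count_met_correlation``.  Rest MET is drawn from the rest
    profile directly (the rest bout defines the MET denominator).  VO2 is
    MET times the participant's resting VO2.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    order = rng.permutation(n)
    groups = np.empty(n, dtype=object)
    groups[order[: config.n_development]] = "development"
    groups[order[config.n_development :]] = "cross_validation"

    lo, hi = config.resting_vo2_range
    resting = rng.uniform(lo, hi, size=n)
    rand_icpt = rng.normal(0.0, config.participant_intercept_sd, size=n)
    rand_slope = rng.normal(0.0, config.participant_slope_sd, size=n)

    rho_ag = config.ap_ag_correlation
    sessions: list[ParticipantSession] = []
    width = max(2, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        a_i = config.count_met_intercept + rand_icpt[i]
        b_i = config.count_met_slope + rand_slope[i]

        epochs: list[EpochRecord] = []
        observation_log: list[tuple[int, int, str]] = []
        t = 0
        prev_posture: str | None = None
        for prof in config.profiles:
            m = prof.n_epochs
            z_ap = rng.standard_normal(m)
            z_shared = rng.standard_normal(m)
            z_ag = rho_ag * z_ap + math.sqrt(1.0 - rho_ag**2) * z_shared
            ap = np.maximum(0.0, prof.ap_count_mean + prof.ap_count_sd * z_ap)
            ag = np.maximum(0.0, prof.ag_count_mean + prof.ag_count_sd * z_ag)

            if prof.label == "rest":
                met = prof.met_mean + prof.met_sd * rng.standard_normal(m)
            else:
                s = config.residual_met_sd
                if s > 0 and prof.ap_count_sd > 0:
                    u = config.count_met_slope * prof.ap_count_sd / s
                    w = _residual_count_weight(u, config.count_met_correlation)
                else:
                    w = 0.0
                z_ind = rng.standard_normal(m)
                eps = s * (w * z_ap + math.sqrt(max(0.0, 1.0 - w * w)) * z_ind)
                met = a_i + b_i * ap + eps
            met = np.maximum(config.met_floor, met)
            vo2 = met * resting[i]

            start = t
            for j in range(m):
                lagged = (
                    prev_posture is not None
                    and j < config.posture_transition_latency
                    and prev_posture != prof.posture_truth
                )
                epochs.append(
                    EpochRecord(
                        time_s=t,
                        activity=prof.label,
                        ap_counts=float(ap[j]),
                        ag_counts=float(ag[j]),
                        vo2=float(vo2[j]),
                        ap_posture=prev_posture if lagged else prof.posture_truth,
                        posture_truth=prof.posture_truth,
                    )
                )
                t += EPOCH_S
            if prof.label != "rest":
                observation_log.append((start, t, prof.posture_truth))
            prev_posture = prof.posture_truth

        sessions.append(
            ParticipantSession(
                participant_id=pid,
                group=str(groups[i]),
                resting_vo2=float(resting[i]),
                epochs=tuple(epochs),
                observation_log=tuple(observation_log),
            )
        )
    return sessions
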