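"""Generator fidelity: determinism, distributional moments, protocol shape."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from metcal import (
    CohortConfigError,
    GeneratorConfig,
    default_config,
    generate_cohort,
)
from metcal.cohort import DEFAULT_INTERCEPT, DEFAULT_SLOPE


def _epochs(cohort, activity):
    return [e for s in cohort for e in s.epochs if e.activity == activity]


class TestDefaultConfig:
    def test_cohort_split_15_15(self, config):
        assert config.n_participants == 30
        assert config.n_development == 15

    @pytest.mark.parametrize(
        "label, field, value",
        [
            ("sit", "ap_count_mean", 5.0),
            ("sit", "ap_count_sd", 8.0),
            ("sit", "ag_count_mean", 0.0),
            ("stand", "ap_count_mean", 15.0),
            ("slow_walk", "ag_count_mean", 632.0),
            ("slow_walk", "ag_count_sd", 174.0),
            ("slow_walk", "ap_count_mean", 3098.0),
            ("brisk_walk", "met_mean", 3.9),
            ("jog", "ap_count_mean", 11086.0),
            ("jog", "met_mean", 8.5),
            ("rest", "met_mean", 1.0),
            ("rest", "ap_count_mean", 0.0),
        ],
    )
    def test_profiles_carry_published_summaries(self, config, label, field, value):
        assert getattr(config.profile(label), field) == value

    def test_fixed_line_passes_through_threshold_anchors(self):
        assert DEFAULT_INTERCEPT + DEFAULT_SLOPE * 2997 == pytest.approx(3.0)
        assert DEFAULT_INTERCEPT + DEFAULT_SLOPE * 7428 == pytest.approx(6.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_development": 30},
            {"n_development": 0},
            {"count_met_correlation": 1.5},
            {"posture_transition_latency": -1},
            {"residual_met_sd": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(CohortConfigError):
            GeneratorConfig(**kwargs)

    def test_negative_profile_sd_rejected(self, config):
        with pytest.raises(CohortConfigError):
            dataclasses.replace(config.profile("sit"), ap_count_sd=-1.0)


class TestGeneration:
    def test_seed_determinism(self, config):
        assert generate_cohort(config) == generate_cohort(config)

    def test_different_seeds_differ(self, config):
        assert generate_cohort(config) != generate_cohort(config.replace(seed=config.seed + 1))

    def test_zero_noise_sitting_counts_exact(self, zero_noise_config):
        cohort = generate_cohort(zero_noise_config)
        assert {e.ap_counts for e in _epochs(cohort, "sit")} == {5.0}

    def test_group_split_disjoint_and_exhaustive(self, cohort, config):
        dev = {s.participant_id for s in cohort if s.group == "development"}
        cv = {s.participant_id for s in cohort if s.group == "cross_validation"}
        assert len(dev) == config.n_development
        assert not dev & cv
        assert len(dev | cv) == config.n_participants

    def test_epoch_grid_and_protocol_length(self, cohort, config):
        total = sum(p.n_epochs for p in config.profiles)
        for s in cohort:
            times = [e.time_s for e in s.epochs]
            assert len(times) == total == 224
            assert times == list(range(0, 15 * total, 15))

    def test_no_negative_counts_or_vo2(self, cohort):
        for s in cohort:
            for e in s.epochs:
                assert e.ap_counts >= 0 and e.ag_counts >= 0 and e.vo2 > 0

    def test_observation_log_covers_non_rest_epochs(self, cohort):
        for s in cohort:
            covered = set()
            last_end = None
            for start, end, _ in s.observation_log:
                if last_end is not None:
                    assert start >= last_end  # non-overlapping
                last_end = end
                covered.update(range(start, end, 15))
            non_rest = {e.time_s for e in s.epochs if e.activity != "rest"}
            assert covered == non_rest


class TestDistributionalFidelity:
    """Monte-Carlo checks of the generator against its own parameters."""

    @pytest.mark.parametrize("activity", ["slow_walk", "brisk_walk", "jog"])
    def test_walking_count_means_match_profiles(self, cohort, config, activity):
        # negligible zero-truncation for locomotor profiles: compare to the
        # raw profile moments, 4 standard errors
        prof = config.profile(activity)
        for attr, mean, sd in [
            ("ap_counts", prof.ap_count_mean, prof.ap_count_sd),
            ("ag_counts", prof.ag_count_mean, prof.ag_count_sd),
        ]:
            x = np.array([getattr(e, attr) for e in _epochs(cohort, activity)])
            assert len(x) >= 500
            assert abs(x.mean() - mean) < 4 * sd / math.sqrt(len(x))

    def test_sitting_counts_match_truncated_moment(self, cohort, config):
        # sitting AP counts 5(8) clipped at zero have analytic mean
        # mu*Phi(mu/sigma) + sigma*phi(mu/sigma)
        prof = config.profile("sit")
        mu, sd = prof.ap_count_mean, prof.ap_count_sd
        expected = mu * stats.norm.cdf(mu / sd) + sd * stats.norm.pdf(mu / sd)
        x = np.array([e.ap_counts for e in _epochs(cohort, "sit")])
        assert abs(x.mean() - expected) < 4 * x.std() / math.sqrt(len(x))

    def test_walking_truncation_fraction_below_1pct(self, cohort):
        for activity in ("slow_walk", "brisk_walk", "jog"):
            x = np.array([e.ap_counts for e in _epochs(cohort, activity)])
            assert (x == 0).mean() < 0.01

    def test_met_means_track_participant_lines(self, cohort, config):
        # MET fidelity is against the generator's own implied mean: the
        # fixed line evaluated at the realized counts (residual is mean-zero)
        for activity in ("slow_walk", "jog"):
            eps = _epochs(cohort, activity)
            by_pid = {}
            for s in cohort:
                for e in s.epochs:
                    if e.activity == activity:
                        by_pid.setdefault(s.participant_id, []).append(
                            e.vo2 / s.resting_vo2
                        )
            met = np.array([m for v in by_pid.values() for m in v])
            counts = np.array([e.ap_counts for e in eps])
            implied = config.count_met_intercept + config.count_met_slope * counts.mean()
            se = met.std() / math.sqrt(len(met))
            assert abs(met.mean() - implied) < 4 * se

    def test_within_activity_count_met_correlation(self, config):
        # pool many epochs at a single activity; the jog profile's natural
        # count-mediated correlation is already ~0.7, the sitting profile
        # needs the residual coupling -- check both land near the target
        cfg = config.replace(seed=11)
        cohort = generate_cohort(cfg)
        for activity in ("sit", "jog"):
            counts, met = [], []
            for s in cohort:
                for e in s.epochs:
                    if e.activity == activity:
                        counts.append(e.ap_counts)
                        met.append(e.vo2 / s.resting_vo2)
            r = np.corrcoef(counts, met)[0, 1]
            assert abs(r - cfg.count_met_correlation) < 0.12

    def test_ap_ag_correlation(self, cohort, config):
        eps = _epochs(cohort, "slow_walk")
        r = np.corrcoef(
            [e.ap_counts for e in eps], [e.ag_counts for e in eps]
        )[0, 1]
        assert abs(r - config.ap_ag_correlation) < 0.05


class TestPostureCorruption:
    def test_corruption_confined_to_latency_window(self, config):
        for latency in (0, 1, 3):
            cohort = generate_cohort(
                config.replace(posture_transition_latency=latency)
            )
            for s in cohort:
                bout_start = None
                prev_activity = None
                for e in s.epochs:
                    if e.activity != prev_activity:
                        bout_start = e.time_s
                        prev_activity = e.activity
                    within = (e.time_s - bout_start) // 15 < latency
                    if e.ap_posture != e.posture_truth:
                        assert within, "corruption outside latency window"
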