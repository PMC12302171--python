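"""R-R sampling law and beat-schedule construction."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from afloop.protocol import Scenario
from afloop.rhythm import (
    IRREGULAR_ANALYSIS_BEATS,
    IRREGULAR_WARMUP_BEATS,
    REGULAR_BEATS,
    BeatSchedule,
    RRDistribution,
    build_schedule,
    regular_schedule,
    sample_rr_intervals,
)

AV_DELAY = 0.16


def truncated_lognormal_mean(dist: RRDistribution) -> float:
    """Numeric-integration oracle for the truncated sampling law's mean."""
    sigma2 = math.log(1.0 + dist.cv**2)
    mu = math.log(dist.mean_rr) - 0.5 * sigma2
    sigma = math.sqrt(sigma2)
    pdf = stats.lognorm(s=sigma, scale=math.exp(mu)).pdf
    lo, hi = dist.bounds
    mass, _ = integrate.quad(pdf, lo, hi)
    first, _ = integrate.quad(lambda x: x * pdf(x), lo, hi)
    return first / mass


class TestSampling:
    def test_zero_cv_is_exactly_regular(self):
        dist = RRDistribution(mean_bpm=61.0, cv=0.0)
        rr = sample_rr_intervals(50, dist, seed=0)
        assert np.all(rr == pytest.approx(60.0 / 61.0))

    @pytest.mark.parametrize("bpm", [61.0, 94.0])
    def test_large_sample_mean_matches_oracle(self, bpm):
        dist = RRDistribution(mean_bpm=bpm, cv=0.24)
        rr = sample_rr_intervals(100_000, dist, seed=123)
        oracle = truncated_lognormal_mean(dist)
        assert rr.mean() == pytest.approx(oracle, rel=5e-3)
        # and the truncated mean stays within 1% of the nominal 60/bpm
        assert abs(rr.mean() - dist.mean_rr) / dist.mean_rr < 0.01

    def test_truncation_bounds_hold(self):
        dist = RRDistribution(mean_bpm=94.0, cv=0.5, bounds=(0.3, 2.0))
        rr = sample_rr_intervals(20_000, dist, seed=5)
        assert rr.min() >= 0.3 and rr.max() <= 2.0

    def test_seeded_determinism(self):
        dist = RRDistribution(mean_bpm=61.0, cv=0.24)
        a = sample_rr_intervals(100, dist, seed=42)
        b = sample_rr_intervals(100, dist, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            RRDistribution(mean_bpm=61.0, cv=-0.1)
        with pytest.raises(ValueError):
            RRDistribution(mean_bpm=0.0)
        with pytest.raises(ValueError):
            sample_rr_intervals(0, RRDistribution(mean_bpm=61.0), seed=1)


class TestSchedules:
    def test_regular_protocol_shape(self):
        sc = Scenario("physiological", "regular", True)
        dist = RRDistribution(mean_bpm=61.0, cv=0.0)
        sched = build_schedule(sc, dist, AV_DELAY, seed=0)
        assert sched.n_beats == REGULAR_BEATS
        assert sched.analysis_beats == (REGULAR_BEATS - 1,)
        assert all(rr == pytest.approx(60.0 / 61.0) for rr in sched.rr_intervals)

    def test_irregular_protocol_shape(self):
        sc = Scenario("physiological", "irregular", True)
        dist = RRDistribution(mean_bpm=61.0, cv=0.24)
        sched = build_schedule(sc, dist, AV_DELAY, seed=3)
        n = IRREGULAR_WARMUP_BEATS + IRREGULAR_ANALYSIS_BEATS
        assert sched.n_beats == n
        assert sched.analysis_beats == tuple(range(IRREGULAR_WARMUP_BEATS, n))
        assert len(set(sched.rr_intervals)) > 1

    def test_irregular_analysed_mean_matches_regular_cycle_length(self):
        # the regular rate level is defined as the average of the irregular
        # sequence, so the intervals feeding the analysed beats average to
        # exactly the regular cycle length
        sc = Scenario("physiological", "irregular", True)
        dist = RRDistribution(mean_bpm=61.0, cv=0.24)
        sched = build_schedule(sc, dist, AV_DELAY, seed=11)
        feed = [sched.preceding_intervals[k] for k in sched.analysis_beats]
        assert np.mean(feed) == pytest.approx(60.0 / 61.0, rel=1e-9)

    def test_atrial_activations_lead_by_av_delay(self):
        sc = Scenario("rapid", "irregular", True)
        dist = RRDistribution(mean_bpm=94.0, cv=0.24)
        sched = build_schedule(sc, dist, AV_DELAY, seed=7)
        for a, v in zip(
            sched.atrial_activation_times, sched.ventricular_activation_times
        ):
            assert v - a == pytest.approx(AV_DELAY)

    def test_atrial_times_absent_without_contraction(self):
        sc = Scenario("physiological", "regular", False)
        dist = RRDistribution(mean_bpm=61.0, cv=0.0)
        assert build_schedule(sc, dist, AV_DELAY, seed=0).atrial_activation_times is None

    def test_schedule_is_pure_function_of_inputs(self):
        sc = Scenario("rapid", "irregular", True)
        dist = RRDistribution(mean_bpm=94.0, cv=0.24)
        s1 = build_schedule(sc, dist, AV_DELAY, seed=9)
        s2 = build_schedule(sc, dist, AV_DELAY, seed=9)
        assert s1 == s2

    def test_activation_times_strictly_increasing(self):
        sched = regular_schedule(94.0, 12, AV_DELAY)
        vt = sched.ventricular_activation_times
        assert all(b > a for a, b in zip(vt, vt[1:]))

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            BeatSchedule(
                rr_intervals=(1.0, -0.5),
                ventricular_activation_times=(0.16, 1.16),
                atrial_activation_times=None,
                warmup_beats=1,
                analysis_beats=(1,),
                mean_rr=1.0,
            )
        with pytest.raises(ValueError):
            BeatSchedule(
                rr_intervals=(1.0, 1.0),
                ventricular_activation_times=(0.16, 1.16),
                atrial_activation_times=None,
                warmup_beats=1,
                analysis_beats=(5,),
                mean_rr=1.0,
            )
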