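"""R-R interval generation and beat schedules.

Regular rhythms use a fixed cycle length of 60/mean_bpm seconds.
AF-like irregular rhythms draw R-R intervals from a lognormal distribution
parameterised by its mean (60/mean_bpm) and coefficient of variation,
truncated by rejection to a physiological band.  The trial protocol maps
scenarios onto schedules: regular arms run 5 beats and analyse the final
one; irregular arms run 3 warm-up intervals followed by 9 analysed beats.

Atrial activations, when present, precede each ventricular activation by
the atrio-ventricular delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RRDistribution",
    "BeatSchedule",
    "sample_rr_intervals",
    "build_schedule",
    "REGULAR_BEATS",
    "IRREGULAR_WARMUP_BEATS",
    "IRREGULAR_ANALYSIS_BEATS",
]

REGULAR_BEATS = 5
IRREGULAR_WARMUP_BEATS = 3
IRREGULAR_ANALYSIS_BEATS = 9


@dataclass(frozen=True)
class RRDistribution:
    """Lognormal R-R interval law with truncation bounds (s)."""

    mean_bpm: float
    cv: float = 0.24
    bounds: tuple[float, float] = (0.3, 2.0)
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.mean_bpm <= 0:
            raise ValueError("mean_bpm must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be ordered")
        if self.family != "lognormal":
            raise ValueError(f"unsupported family {self.family!r}")

    @property
    def mean_rr(self) -> float:
        return 60.0 / self.mean_bpm


def sample_rr_intervals(n: int, dist: RRDistribution, seed) -> np.ndarray:
    """Draw ``n`` seeded R-R intervals (s), truncated to ``dist.bounds``.

    The underlying lognormal is parameterised so its untruncated mean is
    60/mean_bpm and its coefficient of variation is ``dist.cv``; with the
    default bounds the truncation-induced mean shift is well below 1%.
    ``cv = 0`` degenerates to exactly constant intervals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = dist.mean_rr
    if dist.cv == 0.0:
        return np.full(n, m)
    sigma2 = math.log(1.0 + dist.cv**2)
    mu = math.log(m) - 0.5 * sigma2
    sigma = math.sqrt(sigma2)
    rng = np.random.default_rng(seed)
    lo, hi = dist.bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


@dataclass(frozen=True)
class BeatSchedule:
    """Ordered activation times with warm-up/analysis bookkeeping.

    ``rr_intervals[k]`` is the cycle length of beat ``k`` (the time until
    the next ventricular activation); ``preceding_intervals[k]`` the
    diastolic interval before beat ``k`` that drives calcium restitution
    (the nominal mean interval for the first beat).  ``analysis_beats``
    holds 0-based indices of the beats entering the endpoint average.
    """

    rr_intervals: tuple[float, ...]
    ventricular_activation_times: tuple[float, ...]
    atrial_activation_times: tuple[float, ...] | None
    warmup_beats: int
    analysis_beats: tuple[int, ...]
    mean_rr: float

    def __post_init__(self) -> None:
        if any(rr <= 0 for rr in self.rr_intervals):
            raise ValueError("all R-R intervals must be > 0")
        vt = self.ventricular_activation_times
        if len(vt) != len(self.rr_intervals):
            raise ValueError("need one activation time per R-R interval")
        if any(b - a <= 0 for a, b in zip(vt, vt[1:])):
            raise ValueError("activation times must be strictly increasing")
        if self.atrial_activation_times is not None and len(
            self.atrial_activation_times
        ) != len(vt):
            raise ValueError("need one atrial activation per beat")
        if any(not 0 <= k < len(vt) for k in self.analysis_beats):
            raise ValueError("analysis_beats outside the scheduled beats")

    @property
    def n_beats(self) -> int:
        return len(self.rr_intervals)

    @property
    def preceding_intervals(self) -> tuple[float, ...]:
        return (self.mean_rr,) + self.rr_intervals[:-1]

    @property
    def end_time(self) -> float:
        return self.ventricular_activation_times[-1] + self.rr_intervals[-1]


def _make_schedule(
    rr: np.ndarray,
    av_delay: float,
    warmup: int,
    analysis: tuple[int, ...],
    mean_rr: float,
    atrial: bool,
) -> BeatSchedule:
    v_times = av_delay + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    a_times = tuple(v_times - av_delay) if atrial else None
    return BeatSchedule(
        rr_intervals=tuple(float(x) for x in rr),
        ventricular_activation_times=tuple(float(t) for t in v_times),
        atrial_activation_times=a_times,
        warmup_beats=warmup,
        analysis_beats=analysis,
        mean_rr=mean_rr,
    )


def regular_schedule(
    mean_bpm: float, n_beats: int, av_delay: float, *, atrial: bool = True
) -> BeatSchedule:
    """A fixed-rate schedule of ``n_beats`` cycles (final beat analysed).

    Used for calibration settling runs, which may be longer than the
    5-beat regular trial protocol.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    mean_rr = 60.0 / mean_bpm
    rr = np.full(n_beats, mean_rr)
    return _make_schedule(rr, av_delay, n_beats - 1, (n_beats - 1,), mean_rr, atrial)


def build_schedule(
    scenario,
    dist: RRDistribution,
    av_delay: float,
    seed,
) -> BeatSchedule:
    """Turn a factorial scenario into a concrete beat schedule.

    Regular arms: 5 identical cycles, the final beat analysed.  Irregular
    arms: 12 sampled cycles, the final 9 analysed.  Atrial activations are
    present iff the scenario has effective atrial contraction, each leading
    its ventricular activation by ``av_delay``.
    """
    if scenario.regularity not in ("regular", "irregular"):
        raise ValueError(f"unknown regularity {scenario.regularity!r}")
    if av_delay < 0:
        raise ValueError("av_delay must be >= 0")
    if scenario.regularity == "regular":
        rr = np.full(REGULAR_BEATS, dist.mean_rr)
        warmup = REGULAR_BEATS - 1
        analysis = (REGULAR_BEATS - 1,)
    else:
        n = IRREGULAR_WARMUP_BEATS + IRREGULAR_ANALYSIS_BEATS
        rr = sample_rr_intervals(n, dist, seed)
        # rescale the drawn block so that the mean of the diastolic
        # intervals feeding the analysed beats equals the regular arm's
        # cycle length exactly: the regular rate levels are defined as the
        # averages of the irregular sequences, so paired regular/irregular
        # contrasts isolate rhythm shape from mean rate
        feed = slice(IRREGULAR_WARMUP_BEATS - 1, n - 1)
        for _ in range(3):
            rr = np.clip(rr * (dist.mean_rr / rr[feed].mean()), *dist.bounds)
        warmup = IRREGULAR_WARMUP_BEATS
        analysis = tuple(range(IRREGULAR_WARMUP_BEATS, n))
    return _make_schedule(
        rr, av_delay, warmup, analysis, dist.mean_rr, scenario.atrial_contraction
    )
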