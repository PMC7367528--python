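"""Seeded generators for exercise motion traces and breath envelopes.

The generators emulate the behavioural structure of paced resistance
exercise: sinusoid-like repetitions whose half-cycle durations wander around
a target pace, endpoint positions with systematic bias and per-repetition
jitter, additive measurement noise, and exhalation bursts that are either
locked to the movement cycle, free-running, or interrupted by breath-holds.

Each repetition is two half-cycle cosine segments (smooth position, zero
velocity at the endpoints), which matches the near-sinusoidal character of
well-paced lifts and keeps every generated quantity analytically checkable.
A short lead-in/lead-out ramp (hand moving from mid-range into the start
position and back) frames the set so that the set's first and last bottom
positions are genuine interior turning points for the detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .breathing import BreathEnvelope
from .errors import InvalidInputError
from .kinematics import ExerciseKind, MotionTrace, OriginRef, detect_endpoints, PhaseLabel

__all__ = [
    "ExerciserProfile",
    "BreathMode",
    "BreathPattern",
    "MotionTruth",
    "SetRecording",
    "SessionBundle",
    "gen_motion",
    "gen_breath",
    "gen_session",
]

_MIN_HALF_CYCLE_S = 0.5  # physiological floor for a jittered half-cycle


@dataclass(frozen=True)
class ExerciserProfile:
    """Statistical description of one exerciser's set behaviour.

    Defaults are the guideline-perfect exerciser: 3 s concentric, 3 s
    eccentric, 10 repetitions, no jitter or noise, a 400 mm range of motion
    centred 300 mm above the body origin.
    """

    con_time_s: float = 3.0
    ecc_time_s: float = 3.0
    time_jitter_sd_s: float = 0.0
    rom_bias_mm: float = 0.0
    rom_jitter_sd_mm: float = 0.0
    noise_sd_mm: float = 0.0
    n_reps: int = 10
    amplitude_mm: float = 200.0
    midpoint_mm: float = 300.0
    lead_s: float = 1.0

    def __post_init__(self) -> None:
        if self.con_time_s <= 0 or self.ecc_time_s <= 0:
            raise InvalidInputError("target half-cycle durations must be > 0")
        if min(self.time_jitter_sd_s, self.rom_jitter_sd_mm, self.noise_sd_mm) < 0:
            raise InvalidInputError("jitter/noise SDs must be >= 0")
        if self.n_reps < 1:
            raise InvalidInputError("n_reps must be >= 1")
        if self.amplitude_mm <= 0 or self.lead_s <= 0:
            raise InvalidInputError("amplitude_mm and lead_s must be > 0")


class BreathMode(str, Enum):
    PACED_PER_CYCLE = "paced_per_cycle"
    FREE = "free"
    HOLDING = "holding"


@dataclass(frozen=True)
class BreathPattern:
    """Exhalation-envelope generator settings.

    ``paced_per_cycle`` places one exhalation burst per movement cycle,
    centred on the concentric (top) endpoint — breathing in rhythm with the
    movement. ``holding`` additionally silences the envelope inside
    ``hold_intervals`` (a modelled Valsalva breath-hold). ``free`` draws
    burst times independently of the movement.
    """

    mode: BreathMode = BreathMode.PACED_PER_CYCLE
    hold_intervals: tuple[tuple[float, float], ...] = ()
    burst_amp: float = 0.8
    burst_dur_s: float = 2.0
    noise_floor: float = 0.05
    free_interval_mean_s: float = 4.0
    free_interval_sd_s: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", BreathMode(self.mode))
        object.__setattr__(
            self, "hold_intervals",
            tuple(tuple(map(float, iv)) for iv in self.hold_intervals),
        )
        if not 0 < self.burst_amp <= 1:
            raise InvalidInputError("burst_amp must lie in (0, 1]")
        if self.burst_dur_s <= 0:
            raise InvalidInputError("burst_dur_s must be > 0")
        if not 0 <= self.noise_floor < self.burst_amp:
            raise InvalidInputError("noise_floor must lie in [0, burst_amp)")
        ivs = sorted(self.hold_intervals)
        for (a0, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise InvalidInputError("hold_intervals must not overlap")
        for a, b in ivs:
            if b <= a:
                raise InvalidInputError("hold interval end must exceed start")


@dataclass(frozen=True)
class MotionTruth:
    """Ground truth of a generated trace: segment knots and endpoint times."""

    knot_times: np.ndarray   # segment boundaries, starting at 0
    knot_values: np.ndarray  # position at each knot (mm)
    ecc_times: np.ndarray    # eccentric (bottom) endpoint times, incl. set start
    con_times: np.ndarray    # concentric (top) endpoint times
    duration_s: float


def _half_cycle_durations(profile: ExerciserProfile, rng: np.random.Generator) -> np.ndarray:
    """Alternating concentric/eccentric durations, jittered and floored."""
    means = np.empty(2 * profile.n_reps)
    means[0::2] = profile.con_time_s
    means[1::2] = profile.ecc_time_s
    d = means + rng.normal(0.0, profile.time_jitter_sd_s, size=means.size) \
        if profile.time_jitter_sd_s > 0 else means.copy()
    return np.maximum(d, _MIN_HALF_CYCLE_S)


def gen_motion(
    profile: ExerciserProfile,
    rate_hz: float = 30.0,
    seed: int = 0,
    exercise_kind: ExerciseKind = ExerciseKind.BICEP_CURL,
    return_truth: bool = False,
) -> MotionTrace | tuple[MotionTrace, MotionTruth]:
    """Generate one set as a uniformly sampled vertical-position trace.

    The set is ``n_reps`` cosine half-cycle pairs between jittered endpoint
    targets (bottom = midpoint − amplitude, top = midpoint + amplitude, each
    plus ``rom_bias_mm`` and endpoint jitter), framed by ``lead_s`` ramps
    from/to mid-range, with optional white position noise per sample.
    Deterministic for a given (profile, rate_hz, seed).
    """
    if rate_hz <= 0:
        raise InvalidInputError("rate_hz must be > 0")
    rng = np.random.default_rng(seed)
    durations = _half_cycle_durations(profile, rng)

    n_end = 2 * profile.n_reps + 1  # ecc, con, ecc, ..., ecc
    targets = np.empty(n_end)
    targets[0::2] = profile.midpoint_mm - profile.amplitude_mm
    targets[1::2] = profile.midpoint_mm + profile.amplitude_mm
    targets += profile.rom_bias_mm
    if profile.rom_jitter_sd_mm > 0:
        targets += rng.normal(0.0, profile.rom_jitter_sd_mm, size=n_end)

    knot_t = np.concatenate([
        [0.0],
        profile.lead_s + np.concatenate([[0.0], np.cumsum(durations)]),
    ])
    knot_t = np.append(knot_t, knot_t[-1] + profile.lead_s)
    knot_v = np.concatenate([
        [profile.midpoint_mm], targets, [profile.midpoint_mm]])

    duration = float(knot_t[-1])
    n_samples = int(math.floor(duration * rate_hz)) + 1
    t = np.arange(n_samples) / rate_hz
    seg = np.clip(np.searchsorted(knot_t, t, side="right") - 1, 0, len(knot_t) - 2)
    tau = (t - knot_t[seg]) / (knot_t[seg + 1] - knot_t[seg])
    v0, v1 = knot_v[seg], knot_v[seg + 1]
    y = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * tau))
    if profile.noise_sd_mm > 0:
        y = y + rng.normal(0.0, profile.noise_sd_mm, size=y.size)

    origin = OriginRef.HEAD if exercise_kind is ExerciseKind.PECTORAL_FLY \
        else OriginRef.CENTER_OF_MASS
    trace = MotionTrace.from_arrays(
        t, y, exercise_kind=exercise_kind, origin_ref=origin,
        nominal_rate_hz=rate_hz,
    )
    if not return_truth:
        return trace
    endpoint_t = knot_t[1:-1]
    truth = MotionTruth(
        knot_times=knot_t,
        knot_values=knot_v,
        ecc_times=endpoint_t[0::2],
        con_times=endpoint_t[1::2],
        duration_s=duration,
    )
    return trace, truth


def _concentric_times(motion: MotionTrace) -> np.ndarray:
    """Top-of-lift times of a trace, via the turning-point detector."""
    eps = detect_endpoints(motion)
    return np.array([e.time_s for e in eps if e.phase_label is PhaseLabel.CONCENTRIC])


def gen_breath(
    pattern: BreathPattern,
    motion: MotionTrace,
    rate_hz: float = 30.0,
    seed: int = 0,
) -> BreathEnvelope:
    """Generate a breath amplitude envelope matched to a motion trace.

    Exhalations are raised-cosine bursts of peak ``burst_amp`` and width
    ``burst_dur_s`` over a constant ``noise_floor``; in paced mode one burst
    per movement cycle, centred on the concentric endpoint. ``holding``
    zeroes the envelope inside the hold intervals. Deterministic per seed.
    """
    if rate_hz <= 0:
        raise InvalidInputError("rate_hz must be > 0")
    if len(motion) == 0:
        raise InvalidInputError("motion trace is empty")
    rng = np.random.default_rng(seed)
    duration = float(motion.times[-1])
    t = np.arange(int(math.floor(duration * rate_hz)) + 1) / rate_hz

    if pattern.mode is BreathMode.FREE:
        centers = []
        c = 1.0 + rng.uniform(0.0, 2.0)
        while c < duration:
            centers.append(c)
            c += max(1.5, rng.normal(pattern.free_interval_mean_s,
                                     pattern.free_interval_sd_s))
        centers = np.asarray(centers)
    else:
        centers = _concentric_times(motion)

    env = np.full(t.shape, pattern.noise_floor)
    half = pattern.burst_dur_s / 2.0
    for c in centers:
        mask = np.abs(t - c) < half
        bump = pattern.burst_amp * 0.5 * (
            1.0 + np.cos(np.pi * (t[mask] - c) / half))
        env[mask] = np.maximum(env[mask], bump)
    if pattern.mode is BreathMode.HOLDING:
        for a, b in pattern.hold_intervals:
            env[(t >= a) & (t < b)] = 0.0
    return BreathEnvelope(times=t, amplitude=np.clip(env, 0.0, 1.0))


@dataclass(frozen=True)
class SetRecording:
    """One generated set: motion plus matched breath envelope."""

    exercise_kind: ExerciseKind
    set_index: int  # 1-based
    motion: MotionTrace
    breath: BreathEnvelope
    truth: MotionTruth


@dataclass(frozen=True)
class SessionBundle:
    sets: tuple[SetRecording, ...]


def gen_session(
    config: "SessionConfig | None" = None,
    seed: int = 0,
    profile: ExerciserProfile | None = None,
    pattern: BreathPattern | None = None,
    rate_hz: float = 30.0,
) -> SessionBundle:
    """Generate a full session: 3 exercises × ``n_sets`` sets of motion+breath.

    Every set draws from an independent random stream derived
    deterministically from (master seed, exercise index, set index), so
    regenerating any one set does not disturb the others.
    """
    from .session import SessionConfig  # deferred: session imports nothing from here

    if config is None:
        config = SessionConfig()
    if profile is None:
        profile = ExerciserProfile(n_reps=config.n_reps_per_set)
    if pattern is None:
        pattern = BreathPattern()
    recordings: list[SetRecording] = []
    exercises = (ExerciseKind.BICEP_CURL, ExerciseKind.SHOULDER_RAISE,
                 ExerciseKind.PECTORAL_FLY)
    for ex_i, kind in enumerate(exercises):
        for set_i in range(config.n_sets):
            ss = np.random.SeedSequence(entropy=(int(seed), ex_i, set_i))
            sub_m, sub_b = ss.spawn(2)
            motion, truth = gen_motion(
                profile, rate_hz=rate_hz, seed=sub_m,
                exercise_kind=kind, return_truth=True)
            breath = gen_breath(pattern, motion, rate_hz=rate_hz, seed=sub_b)
            recordings.append(SetRecording(
                exercise_kind=kind, set_index=set_i + 1,
                motion=motion, breath=breath, truth=truth))
    return SessionBundle(sets=tuple(recordings))
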