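"""Exhalation detection, breathing-pacer light signal and breath-hold alarm.

A headset microphone records the exerciser's exhalations; the signal is
reduced to a normalized RMS amplitude envelope, exhalations are detected by
hysteresis thresholding, and counted per set (ten per ten-repetition set is
the ideal rhythm — one breath per movement cycle). A triangular "breathing
light" brightens over 3 s (inhale cue) and dims over 3 s (exhale cue).
Breath-holding under strain (the Valsalva manoeuvre, which spikes blood
pressure) is countered by switching the lights off whenever no respiration
is measured for 6 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .sonification import EventKind, FeedbackEvent

__all__ = [
    "BreathEnvelope",
    "ExhalationEvent",
    "BreathDetectorParams",
    "LightState",
    "compute_envelope",
    "detect_exhalations",
    "count_exhalations",
    "pacer_brightness",
    "valsalva_monitor",
]

_SILENCE_EPS = 1e-6  # noise floor guard for all-silent recordings


@dataclass(frozen=True)
class BreathEnvelope:
    """Normalized RMS amplitude envelope of a breath recording."""

    times: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitude", a)
        if t.shape != a.shape or t.ndim != 1:
            raise InvalidInputError("times and amplitude must be 1-D and equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("envelope times must be strictly increasing")
        if len(a) and (a.min() < 0 or a.max() > 1):
            raise InvalidInputError("envelope amplitudes must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ExhalationEvent:
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise InvalidInputError("offset_s must exceed onset_s")


@dataclass(frozen=True)
class BreathDetectorParams:
    """Hysteresis detector settings (envelope units are normalized to 1)."""

    window_s: float = 0.1
    on_threshold: float = 0.2
    off_threshold: float = 0.1
    min_duration_s: float = 0.3
    min_gap_s: float = 0.5

    def __post_init__(self) -> None:
        if not self.off_threshold < self.on_threshold:
            raise InvalidInputError("off_threshold must be below on_threshold")
        if min(self.window_s, self.min_duration_s, self.min_gap_s) <= 0:
            raise InvalidInputError("durations must be > 0")


@dataclass(frozen=True)
class LightState:
    brightness: float
    on: bool

    def __post_init__(self) -> None:
        if not self.on and self.brightness != 0.0:
            raise InvalidInputError("brightness must be 0 while off")
        if not 0.0 <= self.brightness <= 1.0:
            raise InvalidInputError("brightness must lie in [0, 1]")


def compute_envelope(
    audio_samples: Sequence[float],
    sample_rate_hz: float,
    window_s: float = 0.1,
) -> BreathEnvelope:
    """Sliding-RMS envelope of raw audio, normalized by its global maximum.

    The RMS is evaluated on a hop of half the window, so the envelope rate
    is ``2 / window_s`` (20 Hz at the 0.1 s default) regardless of the audio
    sample rate. All-zero audio maps to an all-zero envelope. The
    normalization makes the detector scale-invariant: multiplying the audio
    by any positive constant leaves the envelope unchanged.
    """
    x = np.asarray(audio_samples, dtype=float)
    if x.size == 0:
        raise InvalidInputError("audio must be non-empty")
    if sample_rate_hz <= 0:
        raise InvalidInputError("sample_rate_hz must be > 0")
    win = max(1, int(round(window_s * sample_rate_hz)))
    hop = max(1, win // 2)
    starts = np.arange(0, x.size, hop)
    sq = np.concatenate([[0.0], np.cumsum(x * x)])
    ends = np.minimum(starts + win, x.size)
    rms = np.sqrt((sq[ends] - sq[starts]) / (ends - starts))
    peak = rms.max()
    if peak > _SILENCE_EPS:
        rms = rms / peak
    else:
        rms = np.zeros_like(rms)
    # timestamp at the window centre
    times = (starts + (ends - starts) / 2.0) / sample_rate_hz
    return BreathEnvelope(times=times, amplitude=np.clip(rms, 0.0, 1.0))


def detect_exhalations(
    env: BreathEnvelope, params: BreathDetectorParams | None = None
) -> list[ExhalationEvent]:
    """Detect exhalations by hysteresis thresholding of the envelope.

    An event opens when the amplitude reaches ``on_threshold`` and closes
    when it falls below ``off_threshold`` (or at the end of the recording).
    Events closer than ``min_gap_s`` are merged — a dip inside one breath is
    not two breaths — and events shorter than ``min_duration_s`` are then
    discarded as clicks.
    """
    if params is None:
        params = BreathDetectorParams()
    raw: list[ExhalationEvent] = []
    onset: float | None = None
    for t, a in zip(env.times, env.amplitude):
        if onset is None:
            if a >= params.on_threshold:
                onset = float(t)
        elif a < params.off_threshold:
            if t > onset:
                raw.append(ExhalationEvent(onset, float(t)))
            onset = None
    if onset is not None and len(env) and env.times[-1] > onset:
        raw.append(ExhalationEvent(onset, float(env.times[-1])))

    merged: list[ExhalationEvent] = []
    for ev in raw:
        if merged and ev.onset_s - merged[-1].offset_s < params.min_gap_s:
            merged[-1] = ExhalationEvent(merged[-1].onset_s, ev.offset_s)
        else:
            merged.append(ev)
    return [ev for ev in merged
            if ev.offset_s - ev.onset_s >= params.min_duration_s]


def count_exhalations(
    events: Sequence[ExhalationEvent], set_start_s: float, set_end_s: float
) -> int:
    """Number of exhalations whose onset lies in [set_start_s, set_end_s)."""
    if not set_end_s > set_start_s:
        raise InvalidInputError("set_end_s must exceed set_start_s")
    return sum(1 for ev in events if set_start_s <= ev.onset_s < set_end_s)


def pacer_brightness(
    t: float, period_up_s: float = 3.0, period_down_s: float = 3.0
) -> float:
    """Triangular pacer brightness in [0, 1] at time ``t`` (t >= 0).

    Ramps 0→1 over ``period_up_s`` (inhale cue) then 1→0 over
    ``period_down_s`` (exhale cue), repeating; 6-s period at defaults.
    """
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    if period_up_s <= 0 or period_down_s <= 0:
        raise InvalidInputError("ramp durations must be > 0")
    period = period_up_s + period_down_s
    tau = t % period
    if tau < period_up_s:
        return tau / period_up_s
    return 1.0 - (tau - period_up_s) / period_down_s


def valsalva_monitor(
    events: Sequence[ExhalationEvent],
    horizon_s: float,
    timeout_s: float = 6.0,
) -> list[FeedbackEvent]:
    """Emit lights-off/on events for breath-holds over [0, horizon_s].

    The silence timer is referenced to the end (offset) of the most recent
    exhalation, or to t=0 before any breath is heard. When the timer reaches
    ``timeout_s`` with no intervening exhalation onset, a ``lights_off``
    event fires at exactly reference + timeout; the next exhalation onset
    then fires ``lights_on``. A breath arriving exactly at the deadline
    keeps the lights on.
    """
    if timeout_s <= 0:
        raise InvalidInputError("timeout_s must be > 0")
    out: list[FeedbackEvent] = []
    ref = 0.0
    lights_on = True
    for ev in sorted(events, key=lambda e: e.onset_s):
        if ev.onset_s > horizon_s:
            break
        if lights_on and ev.onset_s > ref + timeout_s:
            out.append(FeedbackEvent(ref + timeout_s, EventKind.LIGHTS_OFF))
            lights_on = False
        if not lights_on:
            out.append(FeedbackEvent(ev.onset_s, EventKind.LIGHTS_ON))
            lights_on = True
        ref = max(ref, ev.offset_s)
    if lights_on and ref + timeout_s <= horizon_s:
        out.append(FeedbackEvent(ref + timeout_s, EventKind.LIGHTS_OFF))
    return out
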