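"""Kinematic processing of a 1-D vertical hand-position signal.

A resistance-exercise repetition recorded by a depth camera reduces, for the
exercises supported here, to the vertical (y) coordinate of one hand sampled
at a nominal 30 Hz. This module smooths that signal with a Kinect-style
double-exponential (Holt) filter, finds the turning points between lifting
(concentric) and lowering (eccentric) phases, assembles repetitions, and
computes the per-set exercise-quality metrics: contraction-time means/SDs and
endpoint-position SDs ("endpoint variation").

All positions are millimetres relative to a body origin (centre of mass, or
the head for the inclined pectoral fly), up positive; all times are seconds
since the start of the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "ExerciseKind",
    "OriginRef",
    "PhaseLabel",
    "RomClass",
    "MotionSample",
    "MotionTrace",
    "SmoothingParams",
    "EndpointEvent",
    "Repetition",
    "SetMetrics",
    "HoltSmoother",
    "TurningPointDetector",
    "smooth_trace",
    "estimate_velocity",
    "detect_endpoints",
    "segment_reps",
    "set_metrics",
]


class ExerciseKind(str, Enum):
    BICEP_CURL = "bicep_curl"
    SHOULDER_RAISE = "shoulder_raise"
    PECTORAL_FLY = "pectoral_fly"


class OriginRef(str, Enum):
    CENTER_OF_MASS = "center_of_mass"
    HEAD = "head"


class PhaseLabel(str, Enum):
    CONCENTRIC = "concentric"  # top-of-lift turning point
    ECCENTRIC = "eccentric"  # bottom turning point


class RomClass(str, Enum):
    SUCCESS = "success"
    OVERSHOOT = "overshoot"
    UNDERSHOOT = "undershoot"


@dataclass(frozen=True)
class MotionSample:
    """One time-stamped vertical hand position."""

    time_s: float
    y_mm: float

    def __post_init__(self) -> None:
        if self.time_s < 0 or not math.isfinite(self.time_s):
            raise InvalidInputError(f"time_s must be finite and >= 0, got {self.time_s}")
        if not math.isfinite(self.y_mm):
            raise InvalidInputError(f"y_mm must be finite, got {self.y_mm}")


@dataclass(frozen=True)
class MotionTrace:
    """Ordered vertical hand-position series for one exercise set.

    For bicep curls and shoulder raises the origin is the exerciser's centre
    of mass; the inclined pectoral fly uses the head as origin (the only
    stable reference while lying inclined), and that pairing is enforced.
    """

    samples: tuple[MotionSample, ...]
    exercise_kind: ExerciseKind = ExerciseKind.BICEP_CURL
    origin_ref: OriginRef = OriginRef.CENTER_OF_MASS
    nominal_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "exercise_kind", ExerciseKind(self.exercise_kind))
        object.__setattr__(self, "origin_ref", OriginRef(self.origin_ref))
        if self.nominal_rate_hz <= 0:
            raise InvalidInputError("nominal_rate_hz must be > 0")
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("sample times must be strictly increasing")
        is_fly = self.exercise_kind is ExerciseKind.PECTORAL_FLY
        if is_fly != (self.origin_ref is OriginRef.HEAD):
            raise InvalidInputError(
                "origin_ref must be 'head' exactly for pectoral_fly "
                f"(got {self.exercise_kind.value} / {self.origin_ref.value})"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([s.time_s for s in self.samples], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray([s.y_mm for s in self.samples], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        times: Iterable[float],
        y: Iterable[float],
        **meta,
    ) -> "MotionTrace":
        samples = tuple(MotionSample(float(t), float(v)) for t, v in zip(times, y, strict=True))
        return cls(samples=samples, **meta)


@dataclass(frozen=True)
class SmoothingParams:
    """Parameters of the Kinect-style joint filter.

    ``smoothing``, ``correction`` and ``prediction`` follow the double
    exponential (Holt) recurrence; ``jitter_radius_mm`` attenuates
    sub-threshold frame-to-frame deviations and ``max_deviation_radius_mm``
    clamps the filtered value to the raw measurement. The capture pipeline's
    configuration string ``0.5 0.8 0.3 0.01 0.01`` gives the defaults below
    (the last two values are metres in the device convention, 10 mm here).
    """

    smoothing: float = 0.5
    correction: float = 0.8
    prediction: float = 0.3
    jitter_radius_mm: float = 10.0
    max_deviation_radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.smoothing <= 1.0:
            raise InvalidInputError("smoothing must be in [0, 1]")
        if not 0.0 <= self.correction <= 1.0:
            raise InvalidInputError("correction must be in [0, 1]")
        if self.prediction < 0:
            raise InvalidInputError("prediction must be >= 0")
        if self.jitter_radius_mm <= 0 or self.max_deviation_radius_mm <= 0:
            raise InvalidInputError("radii must be > 0")

    @classmethod
    def identity(cls) -> "SmoothingParams":
        """A pass-through configuration (output equals input).

        With ``smoothing=0`` the Holt stage copies its input; a vanishing
        jitter radius makes every deviation exceed it (so the jitter blend
        never engages), and a huge deviation radius disables the clamp.
        """
        return cls(smoothing=0.0, correction=0.0, prediction=0.0,
                   jitter_radius_mm=1e-12, max_deviation_radius_mm=1e12)


@dataclass
class EndpointEvent:
    """A detected turning point between lifting and lowering."""

    time_s: float
    y_mm: float
    phase_label: PhaseLabel
    timing_error_s: float | None = None  # actual minus ideal; set after alignment
    rom_class: RomClass | None = None

    def __post_init__(self) -> None:
        self.phase_label = PhaseLabel(self.phase_label)
        if self.rom_class is not None:
            self.rom_class = RomClass(self.rom_class)


@dataclass(frozen=True)
class Repetition:
    """One lift-lower cycle: eccentric start → concentric top → eccentric end."""

    index: int  # 1-based
    concentric_time_s: float
    eccentric_time_s: float
    con_endpoint: EndpointEvent
    ecc_endpoint: EndpointEvent

    def __post_init__(self) -> None:
        if self.concentric_time_s <= 0 or self.eccentric_time_s <= 0:
            raise InvalidInputError("repetition durations must be > 0")
        if self.index < 1:
            raise InvalidInputError("repetition index is 1-based")


@dataclass(frozen=True)
class SetMetrics:
    """Per-set summary of exercise quality."""

    n_reps: int
    mean_con_s: float
    sd_con_s: float
    mean_ecc_s: float
    sd_ecc_s: float
    sd_con_endpoint_mm: float
    sd_ecc_endpoint_mm: float
    exhalation_count: int

    FIELDS = (
        "n_reps", "mean_con_s", "sd_con_s", "mean_ecc_s", "sd_ecc_s",
        "sd_con_endpoint_mm", "sd_ecc_endpoint_mm", "exhalation_count",
    )


class HoltSmoother:
    """Streaming double-exponential smoother with jitter and deviation clamps.

    Per frame, with previous filtered value ``f`` and trend ``b``:

    1. jitter clamp — if ``|x - f| <= jitter_radius`` the raw value is pulled
       toward ``f`` in proportion to the deviation ratio;
    2. Holt update — ``f' = (1 - s)·x* + s·(f + b)``,
       ``b' = c·(f' - f) + (1 - c)·b``;
    3. forward prediction — output ``f' + p·b'``;
    4. deviation clamp — the output is pulled back toward the raw sample so
       it never departs from it by more than ``max_deviation_radius``.

    Strictly causal: each output depends only on samples seen so far.
    """

    def __init__(self, params: SmoothingParams):
        self.params = params
        self._filtered: float | None = None
        self._trend: float = 0.0

    def push(self, y_raw: float) -> float:
        p = self.params
        if self._filtered is None:
            self._filtered = y_raw
            self._trend = 0.0
            return y_raw
        prev = self._filtered
        dev = y_raw - prev
        if abs(dev) <= p.jitter_radius_mm:
            x = prev + dev * (abs(dev) / p.jitter_radius_mm)
        else:
            x = y_raw
        filt = (1.0 - p.smoothing) * x + p.smoothing * (prev + self._trend)
        self._trend = p.correction * (filt - prev) + (1.0 - p.correction) * self._trend
        self._filtered = filt
        out = filt + p.prediction * self._trend
        dev_out = out - y_raw
        if abs(dev_out) > p.max_deviation_radius_mm:
            out = y_raw + math.copysign(p.max_deviation_radius_mm, dev_out)
        return out


def smooth_trace(raw: MotionTrace, params: SmoothingParams | None = None) -> MotionTrace:
    """Apply the Holt joint filter to a trace, preserving timestamps."""
    if params is None:
        params = SmoothingParams()
    if len(raw) < 2:
        raise InvalidInputError("smooth_trace needs at least 2 samples")
    sm = HoltSmoother(params)
    out = [sm.push(s.y_mm) for s in raw.samples]
    return MotionTrace.from_arrays(
        raw.times, out,
        exercise_kind=raw.exercise_kind, origin_ref=raw.origin_ref,
        nominal_rate_hz=raw.nominal_rate_hz,
    )


def estimate_velocity(trace: MotionTrace) -> np.ndarray:
    """Finite-difference velocity, shape (n, 2) of (time_s, v_mm_per_s).

    Central differences at interior samples, one-sided at the boundaries
    (``numpy.gradient`` with the actual, possibly irregular, timestamps).
    """
    if len(trace) < 3:
        raise InvalidInputError("estimate_velocity needs at least 3 samples")
    t = trace.times
    v = np.gradient(trace.y, t)
    return np.column_stack([t, v])


class TurningPointDetector:
    """Streaming zig-zag turning-point detector.

    A turning point is committed only when the signal has moved at least
    ``min_prominence_mm`` toward it (from the previous committed endpoint, or
    from the trace's starting value) AND at least ``min_prominence_mm`` away
    from it afterwards — i.e. only interior extrema confirmed on both sides
    are reported. Consecutive endpoints must additionally be separated by
    ``min_half_period_s``; a reversal confirmed too soon after the previous
    endpoint is treated as jitter and ignored. Ties between equal samples
    resolve to the earliest one (candidate updates are strict comparisons).
    """

    def __init__(self, min_half_period_s: float = 0.5, min_prominence_mm: float = 20.0):
        if min_half_period_s <= 0:
            raise InvalidInputError("min_half_period_s must be > 0")
        if min_prominence_mm < 0:
            raise InvalidInputError("min_prominence_mm must be >= 0")
        self.min_half_period_s = min_half_period_s
        self.min_prominence_mm = min_prominence_mm
        self._start_y: float | None = None
        self._direction: int = 0  # 0 unknown, +1 rising, -1 falling
        self._cand_t: float = 0.0
        self._cand_y: float = 0.0
        self._min_t = self._min_y = 0.0
        self._max_t = self._max_y = 0.0
        self._last_committed_t: float | None = None

    def push(self, t: float, y: float) -> list[EndpointEvent]:
        """Feed one sample; return endpoints confirmed by this sample."""
        prom = self.min_prominence_mm
        if self._start_y is None:
            self._start_y = y
            self._min_t = self._max_t = t
            self._min_y = self._max_y = y
            return []
        out: list[EndpointEvent] = []
        if self._direction == 0:
            if y > self._max_y:
                self._max_t, self._max_y = t, y
            if y < self._min_y:
                self._min_t, self._min_y = t, y
            if self._max_y - y >= prom:
                # falling now; the running max is a turning point only if it
                # was itself reached by a prominent rise from the start
                if self._max_y - self._start_y >= prom:
                    out.append(self._commit(self._max_t, self._max_y, PhaseLabel.CONCENTRIC))
                self._direction = -1
                self._cand_t, self._cand_y = t, y
            elif y - self._min_y >= prom:
                if self._start_y - self._min_y >= prom:
                    out.append(self._commit(self._min_t, self._min_y, PhaseLabel.ECCENTRIC))
                self._direction = 1
                self._cand_t, self._cand_y = t, y
            return out
        if self._direction > 0:
            if y > self._cand_y:
                self._cand_t, self._cand_y = t, y
            elif self._cand_y - y >= prom and self._spaced(self._cand_t):
                out.append(self._commit(self._cand_t, self._cand_y, PhaseLabel.CONCENTRIC))
                self._direction = -1
                self._cand_t, self._cand_y = t, y
        else:
            if y < self._cand_y:
                self._cand_t, self._cand_y = t, y
            elif y - self._cand_y >= prom and self._spaced(self._cand_t):
                out.append(self._commit(self._cand_t, self._cand_y, PhaseLabel.ECCENTRIC))
                self._direction = 1
                self._cand_t, self._cand_y = t, y
        return out

    def _spaced(self, t: float) -> bool:
        return (self._last_committed_t is None
                or t - self._last_committed_t >= self.min_half_period_s)

    def _commit(self, t: float, y: float, label: PhaseLabel) -> EndpointEvent:
        self._last_committed_t = t
        return EndpointEvent(time_s=t, y_mm=y, phase_label=label)


def detect_endpoints(
    trace: MotionTrace,
    min_half_period_s: float = 0.5,
    min_prominence_mm: float = 20.0,
) -> list[EndpointEvent]:
    """Detect alternating concentric/eccentric turning points of a trace.

    The trace is expected to be smoothed already; residual jitter below
    ``min_prominence_mm`` cannot create endpoints. An empty list is a valid
    result (e.g. for a monotone ramp).
    """
    det = TurningPointDetector(min_half_period_s, min_prominence_mm)
    events: list[EndpointEvent] = []
    for s in trace.samples:
        events.extend(det.push(s.time_s, s.y_mm))
    return events


def segment_reps(endpoints: Sequence[EndpointEvent]) -> list[Repetition]:
    """Build repetitions from an alternating endpoint sequence.

    A repetition is an (eccentric, concentric, eccentric) triple; the
    trailing eccentric endpoint doubles as the next repetition's start.
    Endpoints before the first eccentric one and trailing unpaired endpoints
    are dropped.
    """
    for a, b in zip(endpoints, endpoints[1:]):
        if a.phase_label == b.phase_label:
            raise InvalidInputError("endpoint phases must alternate")
    # drop leading concentric endpoint(s) — a set starts lowered
    start = next((i for i, e in enumerate(endpoints)
                  if e.phase_label is PhaseLabel.ECCENTRIC), len(endpoints))
    reps: list[Repetition] = []
    i = start
    while i + 2 < len(endpoints):
        ecc0, con, ecc1 = endpoints[i], endpoints[i + 1], endpoints[i + 2]
        reps.append(Repetition(
            index=len(reps) + 1,
            concentric_time_s=con.time_s - ecc0.time_s,
            eccentric_time_s=ecc1.time_s - con.time_s,
            con_endpoint=con,
            ecc_endpoint=ecc1,
        ))
        i += 2
    return reps


def set_metrics(reps: Sequence[Repetition], exhalations: int = 0) -> SetMetrics:
    """Summarise a set: contraction-time means/SDs and endpoint variation.

    SDs use the sample (n-1) convention; with fewer than two repetitions all
    SDs are reported as 0. An empty repetition list yields all-zero metrics.
    """
    n = len(reps)
    if n == 0:
        return SetMetrics(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, int(exhalations))
    con_t = np.array([r.concentric_time_s for r in reps])
    ecc_t = np.array([r.eccentric_time_s for r in reps])
    con_y = np.array([r.con_endpoint.y_mm for r in reps])
    ecc_y = np.array([r.ecc_endpoint.y_mm for r in reps])

    def sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    return SetMetrics(
        n_reps=n,
        mean_con_s=float(np.mean(con_t)),
        sd_con_s=sd(con_t),
        mean_ecc_s=float(np.mean(ecc_t)),
        sd_ecc_s=sd(ecc_t),
        sd_con_endpoint_mm=sd(con_y),
        sd_ecc_endpoint_mm=sd(ecc_y),
        exhalation_count=int(exhalations),
    )
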