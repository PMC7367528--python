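"""Offline session orchestration: causal streaming over recorded inputs.

``run_session`` replays a recorded (or synthetic) set through the full
feedback chain exactly as a live system would see it: samples are processed
strictly in time order, and every emitted signal value or event at time *t*
depends only on inputs at times ≤ *t*. The pace channel smooths the motion,
detects turning points, keeps the sinusoidal reference model phase-aligned
to them, and maps the velocity difference to a pitch-transposition signal
plus endpoint earcons. The breathing channel detects exhalations, drives
the triangular light pacer, and switches the lights off after 6 s without
respiration.

In the control condition the same metrics are computed but no feedback
events or signals are produced, mirroring an unassisted exercise set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .breathing import (
    BreathDetectorParams,
    BreathEnvelope,
    count_exhalations,
    detect_exhalations,
    pacer_brightness,
    valsalva_monitor,
)
from .errors import InvalidInputError
from .kinematics import (
    EndpointEvent,
    HoltSmoother,
    MotionTrace,
    PhaseLabel,
    Repetition,
    SetMetrics,
    SmoothingParams,
    TurningPointDetector,
    segment_reps,
    set_metrics,
)
from .reference import (
    CalibrationProfile,
    ReferenceModel,
    endpoint_timing_error,
    realign_phase,
    reference_position,
)
from .sonification import (
    EventKind,
    FeedbackEvent,
    PitchMapParams,
    classify_endpoint,
    earcon_for_endpoint,
    pitch_transpose,
    transposed_frequency,
)

__all__ = [
    "Condition",
    "SessionConfig",
    "SessionResult",
    "FeedbackEngine",
    "run_session",
    "summarize",
]


class Condition(str, Enum):
    CONTROL = "control"
    AMBIENT_SONIFICATION = "ambient_sonification"


@dataclass(frozen=True)
class SessionConfig:
    """Complete configuration of one feedback session."""

    condition: Condition = Condition.AMBIENT_SONIFICATION
    n_sets: int = 3
    n_reps_per_set: int = 10
    pitch_params: PitchMapParams = field(default_factory=PitchMapParams)
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    detector: BreathDetectorParams = field(default_factory=BreathDetectorParams)
    calibration: CalibrationProfile = field(
        default_factory=lambda: CalibrationProfile(y_ecc_mm=100.0, y_con_mm=500.0))
    min_half_period_s: float = 0.5
    min_prominence_mm: float = 20.0
    breath_timeout_s: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.n_sets < 1 or self.n_reps_per_set < 1:
            raise InvalidInputError("n_sets and n_reps_per_set must be >= 1")


@dataclass
class SessionResult:
    """Everything one ``run_session`` call produces for a single set."""

    events: list[FeedbackEvent]
    pitch_signal: pd.DataFrame | None  # time_s, transpose_octaves, output_freq_hz
    light_signal: pd.DataFrame | None  # time_s, brightness, on
    metrics: SetMetrics
    endpoints: list[EndpointEvent]
    reps: list[Repetition]


class FeedbackEngine:
    """Causal pace-feedback engine over a motion sample stream.

    Feeding the same samples in chunks of any size yields identical output:
    all state advances one sample at a time. The reference model is created
    at the first detected endpoint and re-anchored at every subsequent one;
    before the model exists the pitch output is neutral (transpose 0).
    Measured and reference velocities are both backward finite differences
    of position at the sample times, so they are directly comparable and a
    movement identical to the reference yields exactly zero transposition.
    """

    def __init__(self, config: SessionConfig):
        self.config = config
        self._smoother = HoltSmoother(config.smoothing)
        self._detector = TurningPointDetector(
            config.min_half_period_s, config.min_prominence_mm)
        self._model: ReferenceModel | None = None
        self._prev: tuple[float, float] | None = None  # (t, y_smoothed)
        self._seen_first_ecc = False
        self._completed_reps = 0
        self._set_complete_emitted = False
        self.endpoints: list[EndpointEvent] = []
        self.events: list[FeedbackEvent] = []
        self.pitch_rows: list[tuple[float, float, float]] = []
        # nominal carrier for the reported output frequency: geometric centre
        # of the melody band
        p = config.pitch_params
        self._carrier_hz = math.sqrt(p.base_low_hz * p.base_high_hz)

    def feed(self, samples: Iterable[tuple[float, float]]) -> None:
        for t, y in samples:
            self._step(float(t), float(y))

    def _step(self, t: float, y_raw: float) -> None:
        cfg = self.config
        y = self._smoother.push(y_raw)
        for ep in self._detector.push(t, y):
            self._on_endpoint(ep)
        transpose = 0.0
        if self._model is not None and self._prev is not None:
            t0, y0 = self._prev
            dt = t - t0
            if dt > 0:
                v_meas = (y - y0) / dt
                v_ref = (reference_position(self._model, t)
                         - reference_position(self._model, t0)) / dt
                transpose = pitch_transpose(v_meas, v_ref, cfg.pitch_params)
        freq = transposed_frequency(self._carrier_hz, transpose)
        self.pitch_rows.append((t, transpose, freq))
        self._prev = (t, y)

    def _on_endpoint(self, ep: EndpointEvent) -> None:
        cfg = self.config
        ep.rom_class = classify_endpoint(ep.y_mm, cfg.calibration, ep.phase_label)
        if self._model is not None:
            ep.timing_error_s = endpoint_timing_error(self._model, ep)
        in_rep = self._seen_first_ecc
        if ep.phase_label is PhaseLabel.ECCENTRIC and not self._seen_first_ecc:
            self._seen_first_ecc = True
        self.endpoints.append(ep)
        if self._model is None:
            self._model = realign_phase(
                ReferenceModel(calibration=cfg.calibration), ep)
        else:
            self._model = realign_phase(self._model, ep)
        if not in_rep:
            return  # the set's starting position is not a reached endpoint
        earcon = earcon_for_endpoint(ep)
        if earcon is not None:
            self.events.append(earcon)
        if ep.phase_label is PhaseLabel.ECCENTRIC:
            self._completed_reps += 1
            if (self._completed_reps == cfg.n_reps_per_set
                    and not self._set_complete_emitted):
                self._set_complete_emitted = True
                self.events.append(FeedbackEvent(
                    time_s=ep.time_s,
                    kind=EventKind.EARCON_SET_COMPLETE,
                    payload={"n_reps": self._completed_reps},
                ))

    @property
    def reps(self) -> list[Repetition]:
        return segment_reps(self.endpoints)


def _light_signal(
    times: np.ndarray,
    light_events: Sequence[FeedbackEvent],
) -> pd.DataFrame:
    """Pacer brightness at the given times, gated by lights_off/on events.

    After each lights_on the pacer restarts from minimum brightness, cueing
    a fresh inhale ramp.
    """
    off_t = [e.time_s for e in light_events if e.kind is EventKind.LIGHTS_OFF]
    on_t = [e.time_s for e in light_events if e.kind is EventKind.LIGHTS_ON]
    rows = []
    for t in times:
        n_off = sum(1 for x in off_t if x <= t)
        n_on_resume = sum(1 for x in on_t if x <= t)
        is_on = n_off <= n_on_resume
        if is_on:
            origin = max([0.0] + [x for x in on_t if x <= t])
            rows.append((t, pacer_brightness(t - origin), True))
        else:
            rows.append((t, 0.0, False))
    return pd.DataFrame(rows, columns=["time_s", "brightness", "on"])


def run_session(
    motion: MotionTrace,
    breath: BreathEnvelope,
    config: SessionConfig | None = None,
) -> SessionResult:
    """Run one set through the feedback engine, causally, start to finish.

    Returns the time-ordered event log, the pitch and light signals sampled
    at the motion timestamps, and the set's quality metrics. In the control
    condition the event log is empty and no signals are produced, but the
    metrics are identical to an ambient_sonification run on the same inputs.
    """
    if config is None:
        config = SessionConfig()
    if len(motion) < 2:
        raise InvalidInputError("motion trace needs at least 2 samples")
    if len(breath) == 0:
        raise InvalidInputError("breath envelope is empty")
    if motion.times[0] < 0 or breath.times[0] < 0:
        raise InvalidInputError("inputs must share a clock starting at 0")

    horizon = float(motion.times[-1])
    engine = FeedbackEngine(config)
    engine.feed(zip(motion.times, motion.y))

    exhalations = detect_exhalations(breath, config.detector)
    light_events = valsalva_monitor(exhalations, horizon, config.breath_timeout_s)
    n_breaths = count_exhalations(exhalations, 0.0, horizon)

    reps = engine.reps
    metrics = set_metrics(reps, exhalations=n_breaths)

    if config.condition is Condition.CONTROL:
        return SessionResult(
            events=[], pitch_signal=None, light_signal=None,
            metrics=metrics, endpoints=engine.endpoints, reps=reps)

    events = sorted(engine.events + list(light_events), key=lambda e: e.time_s)
    pitch = pd.DataFrame(
        engine.pitch_rows, columns=["time_s", "transpose_octaves", "output_freq_hz"])
    light = _light_signal(motion.times, light_events)
    return SessionResult(
        events=events, pitch_signal=pitch, light_signal=light,
        metrics=metrics, endpoints=engine.endpoints, reps=reps)


@dataclass(frozen=True)
class SetRun:
    """Identifier + result for one processed set, as fed to ``summarize``."""

    exercise: str
    set_index: int
    condition: Condition
    result: SessionResult


_EVENT_COUNT_COLS = {
    "n_success_earcons": (EventKind.EARCON_SUCCESS_CON, EventKind.EARCON_SUCCESS_ECC),
    "n_corrective_earcons": (EventKind.EARCON_CORRECTIVE_CON,
                             EventKind.EARCON_CORRECTIVE_ECC),
    "n_set_complete": (EventKind.EARCON_SET_COMPLETE,),
    "n_lights_off": (EventKind.LIGHTS_OFF,),
}


def summarize(runs: Sequence[SetRun]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-set metrics table plus a condition-level aggregate.

    Returns ``(per_set, by_condition)``: one row per (exercise, set,
    condition) with the SetMetrics fields and event counts, and a
    condition-level table of means and sample SDs of the numeric metrics.
    """
    if len(runs) == 0:
        raise InvalidInputError("summarize needs at least one set")
    rows = []
    for r in runs:
        m = r.result.metrics
        row = {
            "exercise": str(getattr(r.exercise, "value", r.exercise)),
            "set_index": r.set_index,
            "condition": Condition(r.condition).value,
        }
        row.update({f: getattr(m, f) for f in SetMetrics.FIELDS})
        for col, kinds in _EVENT_COUNT_COLS.items():
            row[col] = sum(1 for e in r.result.events if e.kind in kinds)
        rows.append(row)
    per_set = pd.DataFrame(rows)
    numeric = [c for c in per_set.columns
               if c not in ("exercise", "set_index", "condition")]
    by_condition = (per_set.groupby("condition")[numeric]
                    .agg(["mean", "std"]))
    by_condition.columns = [f"{a}_{b}" for a, b in by_condition.columns]
    by_condition = by_condition.reset_index()
    return per_set, by_condition
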