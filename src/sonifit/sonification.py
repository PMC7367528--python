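"""Velocity-error pitch mapping and earcon event logic.

The pace channel plays a looped melody spanning 185–247 Hz and transposes it
by at most one octave either way (92.5–494 Hz overall), proportionally to
the difference between measured and ideal movement velocity. Discrete events
(endpoint reached, range-of-motion violation, set completed) are conveyed by
earcons — brief characteristic sounds, the auditory analogue of icons.

This module emits control values and event records, not rendered audio; the
optional demo renderer lives in :mod:`sonifit.render`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Sequence

from .errors import InvalidInputError
from .kinematics import EndpointEvent, PhaseLabel, Repetition, RomClass
from .reference import CalibrationProfile

__all__ = [
    "PitchDirection",
    "PitchMapParams",
    "PitchState",
    "EventKind",
    "FeedbackEvent",
    "EARCON_PITCH_HZ",
    "pitch_transpose",
    "transposed_frequency",
    "classify_endpoint",
    "emit_earcons",
]


class PitchDirection(str, Enum):
    FASTER_IS_HIGHER = "faster_is_higher"
    FASTER_IS_LOWER = "faster_is_lower"


@dataclass(frozen=True)
class PitchMapParams:
    """Linear velocity-difference → transposition mapping.

    ``dv_sat_mm_per_s`` is the velocity-difference magnitude at which the
    transposition saturates at a full octave. Its natural scale is the
    reference model's peak velocity (2*pi*A/period): a complete stop or a
    doubled pace then just reaches the clamp.
    """

    base_low_hz: float = 185.0
    base_high_hz: float = 247.0
    dv_sat_mm_per_s: float = 2.0 * math.pi * 200.0 / 6.0
    direction: PitchDirection = PitchDirection.FASTER_IS_HIGHER
    quantize_semitones: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", PitchDirection(self.direction))
        if not 0 < self.base_low_hz < self.base_high_hz:
            raise InvalidInputError("need 0 < base_low_hz < base_high_hz")
        if self.dv_sat_mm_per_s <= 0:
            raise InvalidInputError("dv_sat_mm_per_s must be > 0")


@dataclass(frozen=True)
class PitchState:
    """Momentary pitch output: octave offset and sounding frequency."""

    transpose_octaves: float
    output_freq_hz: float


class EventKind(str, Enum):
    EARCON_SUCCESS_CON = "earcon_success_con"
    EARCON_SUCCESS_ECC = "earcon_success_ecc"
    EARCON_CORRECTIVE_CON = "earcon_corrective_con"
    EARCON_CORRECTIVE_ECC = "earcon_corrective_ecc"
    EARCON_SET_COMPLETE = "earcon_set_complete"
    LIGHTS_OFF = "lights_off"
    LIGHTS_ON = "lights_on"


# Nominal earcon pitches (payload metadata only; concentric variants sit a
# fifth above their eccentric counterparts so "top" events sound higher).
EARCON_PITCH_HZ: dict[EventKind, float] = {
    EventKind.EARCON_SUCCESS_CON: 660.0,
    EventKind.EARCON_SUCCESS_ECC: 440.0,
    EventKind.EARCON_CORRECTIVE_CON: 622.0,
    EventKind.EARCON_CORRECTIVE_ECC: 415.0,
}


@dataclass(frozen=True)
class FeedbackEvent:
    """A timed discrete feedback event (earcon or light switch)."""

    time_s: float
    kind: EventKind
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))


def pitch_transpose(v_meas: float, v_ref: float, params: PitchMapParams) -> float:
    """Map a velocity difference to a transposition in octaves, in [-1, 1].

    Linear in (v_meas - v_ref) up to ``dv_sat``, clamped at one octave; with
    the default polarity, moving faster than the reference raises pitch.
    Optionally snapped to the nearest semitone (1/12 octave).
    """
    x = (v_meas - v_ref) / params.dv_sat_mm_per_s
    if params.direction is PitchDirection.FASTER_IS_LOWER:
        x = -x
    x = max(-1.0, min(1.0, x))
    if params.quantize_semitones:
        x = round(x * 12.0) / 12.0
    return x


def transposed_frequency(base_freq_hz: float, transpose_octaves: float) -> float:
    """Frequency of ``base_freq_hz`` shifted by ``transpose_octaves``."""
    if not -1.0 <= transpose_octaves <= 1.0:
        raise InvalidInputError("transpose_octaves must lie in [-1, 1]")
    return base_freq_hz * 2.0 ** transpose_octaves


def classify_endpoint(
    y_mm: float, cal: CalibrationProfile, phase_label: PhaseLabel
) -> RomClass:
    """Classify a reached endpoint against the calibrated target band.

    ``success`` within ±tolerance of the target; ``overshoot`` beyond the
    target in the movement direction (above the top target for concentric,
    below the bottom target for eccentric); ``undershoot`` otherwise.
    """
    phase_label = PhaseLabel(phase_label)
    target = cal.y_con_mm if phase_label is PhaseLabel.CONCENTRIC else cal.y_ecc_mm
    if abs(y_mm - target) <= cal.tolerance_mm:
        return RomClass.SUCCESS
    past = y_mm > target if phase_label is PhaseLabel.CONCENTRIC else y_mm < target
    return RomClass.OVERSHOOT if past else RomClass.UNDERSHOOT


_EARCON_FOR = {
    (PhaseLabel.CONCENTRIC, RomClass.SUCCESS): EventKind.EARCON_SUCCESS_CON,
    (PhaseLabel.ECCENTRIC, RomClass.SUCCESS): EventKind.EARCON_SUCCESS_ECC,
    (PhaseLabel.CONCENTRIC, RomClass.OVERSHOOT): EventKind.EARCON_CORRECTIVE_CON,
    (PhaseLabel.ECCENTRIC, RomClass.OVERSHOOT): EventKind.EARCON_CORRECTIVE_ECC,
}


def earcon_for_endpoint(ep: EndpointEvent) -> FeedbackEvent | None:
    """The earcon a classified endpoint triggers, or None for undershoot.

    Reaching the band or going too far both produce sound (success vs
    corrective); falling short produces silence.
    """
    if ep.rom_class is None:
        raise InvalidInputError("endpoint must be classified first")
    kind = _EARCON_FOR.get((ep.phase_label, ep.rom_class))
    if kind is None:
        return None
    payload: dict[str, Any] = {
        "pitch_hz": EARCON_PITCH_HZ[kind],
        "rom_class": ep.rom_class.value,
        "y_mm": ep.y_mm,
    }
    if ep.timing_error_s is not None:
        payload["timing_error_s"] = ep.timing_error_s
    return FeedbackEvent(time_s=ep.time_s, kind=kind, payload=payload)


def emit_earcons(
    endpoints: Sequence[EndpointEvent],
    set_size: int = 10,
) -> list[FeedbackEvent]:
    """Turn a classified, time-ordered endpoint stream into earcon events.

    ``endpoints`` are the endpoints *reached during repetitions* (the set's
    starting bottom position is not a reached endpoint and must not be
    included). Each eccentric endpoint completes a repetition; when the
    completed count reaches ``set_size`` a single set-complete earcon is
    emitted at that endpoint's time.
    """
    events: list[FeedbackEvent] = []
    completed = 0
    for ep in endpoints:
        ev = earcon_for_endpoint(ep)
        if ev is not None:
            events.append(ev)
        if ep.phase_label is PhaseLabel.ECCENTRIC:
            completed += 1
            if completed == set_size:
                events.append(FeedbackEvent(
                    time_s=ep.time_s,
                    kind=EventKind.EARCON_SET_COMPLETE,
                    payload={"n_reps": completed},
                ))
    return events
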