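"""Phase-aligned sinusoidal reference model of an ideal repetition.

Guideline-conform resistance movement (3 s concentric, 3 s eccentric) traced
against time is close to a sinusoid, so the ideal movement is modelled as

    y_ref(t) = midpoint - amplitude * cos(2*pi*(t - phase_anchor)/period)

with period 6 s by default. ``phase_anchor`` is a time at which the model
sits at the eccentric (bottom) endpoint moving upward; it is re-anchored at
every detected endpoint so pace feedback always refers to the current
half-cycle rather than accumulating drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidInputError
from .kinematics import EndpointEvent, PhaseLabel

__all__ = [
    "CalibrationProfile",
    "ReferenceModel",
    "reference_position",
    "reference_velocity",
    "realign_phase",
    "endpoint_timing_error",
]


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-user range-of-motion calibration.

    ``tolerance_mm`` is the half-width of the success band around each
    endpoint target (default 20 mm, roughly 5-10 % of a typical arm-exercise
    range of motion).
    """

    y_ecc_mm: float
    y_con_mm: float
    tolerance_mm: float = 20.0

    def __post_init__(self) -> None:
        if not self.y_con_mm > self.y_ecc_mm:
            raise InvalidInputError("y_con_mm must exceed y_ecc_mm")
        if self.tolerance_mm < 0:
            raise InvalidInputError("tolerance_mm must be >= 0")

    @property
    def midpoint_mm(self) -> float:
        return 0.5 * (self.y_con_mm + self.y_ecc_mm)

    @property
    def amplitude_mm(self) -> float:
        return 0.5 * (self.y_con_mm - self.y_ecc_mm)


@dataclass(frozen=True)
class ReferenceModel:
    """Ideal sinusoid: calibration geometry plus period and phase anchor."""

    calibration: CalibrationProfile
    period_s: float = 6.0
    phase_anchor_s: float = 0.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise InvalidInputError("period_s must be > 0")

    @property
    def peak_velocity_mm_s(self) -> float:
        """Largest |velocity| of the model: 2*pi*A/period (pi*A/3 at 6 s)."""
        return 2.0 * math.pi * self.calibration.amplitude_mm / self.period_s


def reference_position(model: ReferenceModel, t: float) -> float:
    """Ideal position (mm) at time ``t``."""
    cal = model.calibration
    phase = 2.0 * math.pi * (t - model.phase_anchor_s) / model.period_s
    return cal.midpoint_mm - cal.amplitude_mm * math.cos(phase)


def reference_velocity(model: ReferenceModel, t: float) -> float:
    """Ideal velocity (mm/s) at time ``t``; positive while lifting."""
    cal = model.calibration
    omega = 2.0 * math.pi / model.period_s
    return cal.amplitude_mm * omega * math.sin(omega * (t - model.phase_anchor_s))


def realign_phase(model: ReferenceModel, endpoint: EndpointEvent) -> ReferenceModel:
    """Re-anchor the model so it reaches ``endpoint``'s extremum at its time.

    Idempotent: realigning twice on the same endpoint changes nothing.
    """
    if endpoint.phase_label is PhaseLabel.ECCENTRIC:
        anchor = endpoint.time_s
    else:
        anchor = endpoint.time_s - model.period_s / 2.0
    return replace(model, phase_anchor_s=anchor)


def endpoint_timing_error(model: ReferenceModel, endpoint: EndpointEvent) -> float:
    """Actual minus ideal endpoint time, in seconds; positive means late.

    The ideal times for an endpoint type form a lattice with spacing
    ``period_s``; the error is measured to the lattice point nearest the
    observed time, so it lies in (-period/2, period/2].
    """
    if endpoint.phase_label is PhaseLabel.ECCENTRIC:
        base = model.phase_anchor_s
    else:
        base = model.phase_anchor_s + model.period_s / 2.0
    k = round((endpoint.time_s - base) / model.period_s)
    return endpoint.time_s - (base + k * model.period_s)
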