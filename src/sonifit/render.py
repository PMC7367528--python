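"""Convenience audio rendering of the pitch signal and earcons to WAV.

Strictly a demo aid: the engine's contract is control values and events,
not produced sound. The pitch signal is rendered as a single sine carrier
whose instantaneous frequency follows ``output_freq_hz`` (phase-continuous
via cumulative integration); earcons are short enveloped sine beeps at the
nominal pitch carried in their payload.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .sonification import EARCON_PITCH_HZ, EventKind, FeedbackEvent

__all__ = ["render_session_audio"]

_SET_COMPLETE_PITCH_HZ = 880.0
_EARCON_DUR_S = 0.15


def render_session_audio(
    pitch_signal: pd.DataFrame,
    events: Sequence[FeedbackEvent],
    path: str | Path,
    sample_rate_hz: int = 22050,
    gain: float = 0.4,
) -> None:
    """Render pitch signal plus earcon beeps into a 16-bit mono WAV."""
    t_end = float(pitch_signal["time_s"].iloc[-1]) + 0.5
    n = int(t_end * sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    freq = np.interp(t, pitch_signal["time_s"], pitch_signal["output_freq_hz"])
    phase = 2.0 * np.pi * np.cumsum(freq) / sample_rate_hz
    audio = gain * np.sin(phase)

    beep_n = int(_EARCON_DUR_S * sample_rate_hz)
    beep_t = np.arange(beep_n) / sample_rate_hz
    envelope = np.hanning(beep_n)
    for e in events:
        f = e.payload.get("pitch_hz") or EARCON_PITCH_HZ.get(e.kind)
        if e.kind is EventKind.EARCON_SET_COMPLETE:
            f = _SET_COMPLETE_PITCH_HZ
        if f is None:  # light events carry no sound
            continue
        i0 = int(e.time_s * sample_rate_hz)
        if i0 >= n:
            continue
        seg = (gain * envelope * np.sin(2 * np.pi * f * beep_t))[: n - i0]
        audio[i0:i0 + len(seg)] += seg

    audio = np.clip(audio, -1.0, 1.0)
    wavfile.write(Path(path), sample_rate_hz, (audio * 32767).astype(np.int16))
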