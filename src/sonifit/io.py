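"""Plain-text I/O: CSV signals, JSON configs and JSON-lines event logs.

Motion traces travel as a two-column CSV (``time_s,y_mm``) with the
exercise metadata in a JSON sidecar; breath input is either a mono WAV file
or a precomputed envelope CSV (``time_s,amplitude``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .breathing import BreathEnvelope
from .errors import InvalidInputError
from .kinematics import MotionTrace, SetMetrics
from .sonification import EventKind, FeedbackEvent

__all__ = [
    "write_motion_csv", "read_motion_csv",
    "write_envelope_csv", "read_envelope_csv",
    "read_breath_wav",
    "write_events_jsonl", "read_events_jsonl",
    "write_metrics_csv",
]


def write_motion_csv(trace: MotionTrace, path: str | Path,
                     sidecar: bool = True) -> None:
    """Write a trace as ``time_s,y_mm`` CSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "y_mm": trace.y}).to_csv(path, index=False)
    if sidecar:
        meta = {
            "exercise_kind": trace.exercise_kind.value,
            "origin_ref": trace.origin_ref.value,
            "nominal_rate_hz": trace.nominal_rate_hz,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_motion_csv(path: str | Path, **meta_override: Any) -> MotionTrace:
    """Read a motion CSV; metadata from the sidecar JSON, overridable."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "y_mm"):
        if col not in df.columns:
            raise InvalidInputError(f"motion CSV missing column {col!r}")
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    meta.update(meta_override)
    return MotionTrace.from_arrays(df["time_s"].to_numpy(),
                                   df["y_mm"].to_numpy(), **meta)


def write_envelope_csv(env: BreathEnvelope, path: str | Path) -> None:
    pd.DataFrame({"time_s": env.times, "amplitude": env.amplitude}).to_csv(
        path, index=False)


def read_envelope_csv(path: str | Path) -> BreathEnvelope:
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise InvalidInputError(f"envelope CSV missing column {col!r}")
    return BreathEnvelope(times=df["time_s"].to_numpy(),
                          amplitude=df["amplitude"].to_numpy())


def read_breath_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Read a WAV file as (sample_rate_hz, mono float samples in [-1, 1])."""
    rate, data = wavfile.read(path)
    x = np.asarray(data)
    if x.ndim == 2:  # average channels to mono
        x = x.mean(axis=1)
    if np.issubdtype(x.dtype, np.integer):
        x = x.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        x = x.astype(float)
    return float(rate), x


def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_events_jsonl(events: Sequence[FeedbackEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            fh.write(json.dumps({
                "time_s": float(e.time_s),
                "kind": e.kind.value,
                "payload": {k: _jsonable(v) for k, v in e.payload.items()},
            }) + "\n")


def read_events_jsonl(path: str | Path) -> list[FeedbackEvent]:
    events = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        events.append(FeedbackEvent(time_s=d["time_s"], kind=EventKind(d["kind"]),
                                    payload=d.get("payload", {})))
    return events


def write_metrics_csv(rows: pd.DataFrame | Sequence[SetMetrics],
                      path: str | Path) -> None:
    """Write per-set metrics (DataFrame, or a plain sequence of SetMetrics)."""
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame([dataclasses.asdict(m) for m in rows])
    rows.to_csv(path, index=False)
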