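# Methods

This note documents the models and procedures implemented in `sonifit`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data validation does and does not show.

## Signal model and smoothing

Input is a single vertical coordinate `y(t)` in millimetres, up positive,
relative to a body origin (centre of mass; the head for the inclined
pectoral fly, the only stable reference while lying inclined), nominally
30 samples/s. Timestamps are carried explicitly and all durations are
computed from them, never from sample counts, so frame jitter in real
captures is tolerated.

Smoothing uses the Kinect-convention jitter-clamped double-exponential
(Holt) filter. With previous filtered value `f`, trend `b`, raw sample `x`,
and parameters *smoothing* `s`, *correction* `c`, *prediction* `p`,
*jitter radius* `r_j`, *max deviation radius* `r_d`:

1. if `|x − f| ≤ r_j`, blend `x ← f + (x − f)·|x − f|/r_j` (small deviations
   are attenuated toward the filter state in proportion to their size);
2. `f′ = (1 − s)·x + s·(f + b)`; `b′ = c·(f′ − f) + (1 − c)·b`;
3. output `f′ + p·b′`, finally clamped to within `r_d` of the raw sample.

Defaults are the capture pipeline's configuration `s=0.5, c=0.8, p=0.3,
r_j=r_d=0.01 m` (10 mm — the device works in metres). The exact internals of
the original vendor plug-in are not public; this recurrence is the standard,
well-documented reading of those five parameters and is frozen here as a
design choice. Note an occasionally surprising consequence of step 1: the
pass-through limit of the filter is `s=0` with a *vanishing* jitter radius
(`SmoothingParams.identity()`), because a large radius attenuates every
deviation. The filter is strictly causal, which the tests assert by prefix
invariance.

## Turning points and repetitions

Endpoints (turning points between lifting and lowering) are detected by a
streaming zig-zag scan: a candidate extremum is committed as an endpoint
only when the signal has travelled at least `min_prominence_mm` (default
20 mm) *toward* it and then at least the same distance *away* from it, and
lies at least `min_half_period_s` (default 0.5 s) after the previous
endpoint. Reversals confirmed too soon after the previous endpoint are
treated as jitter and ignored; ties between equal samples resolve to the
earliest. Only interior extrema confirmed on both sides are reported — the
first and last samples of a recording are never endpoints, which is why the
synthetic generator frames each set with a short approach/rack ramp (below).

A repetition is an (eccentric, concentric, eccentric) endpoint triple; the
trailing bottom endpoint starts the next repetition. Sets are assumed to
begin and end lowered. Concentric/eccentric contraction times are plain
time deltas between consecutive endpoints. Set metrics are the means and
sample SDs (n−1; the conventional choice — reported simply as "SD" in this
literature) of the contraction times and of the endpoint positions
("endpoint variation", mm), plus the exhalation count.

## Reference model and pitch mapping

The ideal movement is `y_ref(t) = m − A·cos(2π(t − φ)/T)`, `T = 6 s`
(3 s concentric + 3 s eccentric), with `m` and `A` from a per-user
calibration (`y_ecc`, `y_con`, success half-band `tolerance_mm`, default
20 mm ≈ 5–10 % of a typical arm range of motion). The phase `φ` is
re-anchored at **every** detected endpoint rather than continuously: pace
corrections then affect the sound almost immediately while error feedback
stays local to the current half-cycle. The endpoint timing error is the
observed endpoint time minus the nearest ideal time for that endpoint type
(positive = late); it is logged in the event payload and realization of the
phase update, nothing else.

Pitch: `transpose = clamp(Δv / Δv_sat, −1, +1)` octaves, where
`Δv = ẏ − ẏ_ref`. `Δv_sat` defaults to the reference peak velocity
`2πA/T` (≈ 209 mm/s for A = 200 mm), so a complete stop or a doubled pace
just reaches the one-octave clamp. Polarity (faster ⇒ higher, the default)
and semitone quantization are configurable; transposition is continuous by
default since the original control is a dial. Applied to a melody spanning
185–247 Hz this yields 92.5–494 Hz overall. Inside the streaming engine
both `ẏ` and `ẏ_ref` are *backward* finite differences at the sample
times — causal, and identical discretizations, so a movement that matches
the reference exactly yields transpose ≡ 0 rather than an O(Δt) residual.
The offline `estimate_velocity` helper uses central differences instead
(more accurate, but needs the future sample). Before the first endpoint is
detected there is no phase anchor and the pitch output is neutral. The
reported `output_freq_hz` applies the transposition to the geometric centre
of the melody band (√(185·247) ≈ 213.8 Hz), a neutral carrier choice.

Endpoint classification against the calibration band: `success` within
±tolerance of the target, `overshoot` beyond it in the movement direction,
`undershoot` otherwise. Success and overshoot trigger earcons (concentric
variants carry a higher nominal pitch: 660/622 Hz vs 440/415 Hz — metadata
only, no sound design is mandated); undershoot is deliberately silent. The
set's starting bottom position is not a reached endpoint and triggers
nothing. A distinct earcon fires when the completed-repetition count
reaches the configured set size (default 10).

## Breathing channel

Breath audio is reduced to an RMS envelope (0.1 s window, half-window hop)
normalized by its global maximum (an ε = 1e−6 floor guards all-silent
recordings), making detection invariant to recording gain. Exhalations are
hysteresis crossings: open at 0.2, close at 0.1 (normalized units); events
closer than 0.5 s are merged *before* events shorter than 0.3 s are
discarded, so two fragments of one interrupted exhalation survive as one
event. Counting uses a half-open window [set start, set end). Ten
exhalations over a ten-repetition set — one per 6-s cycle — is the ideal
rhythm.

The light pacer is a triangular wave: brightness 0→1 over 3 s and 1→0 over
3 s. The breath-hold monitor emits `lights_off` exactly 6 s after the
*offset* of the most recent exhalation (or after t = 0 if none was heard) —
"no respiration for 6 s" reads most naturally as 6 s of silence — and
`lights_on` at the next exhalation onset, after which the pacer restarts
from minimum brightness to re-cue an inhale. A breath arriving exactly at
the deadline keeps the lights on. The physical setup's three lamps are
modelled as one logical channel since they are driven identically.

## Synthetic data

`gen_motion` concatenates cosine half-cycle segments between jittered
endpoint targets: durations ~ N(target, `time_jitter_sd_s`²) floored at
0.5 s; targets `m ± A` plus `rom_bias_mm` and N(0, `rom_jitter_sd_mm`²);
white position noise per sample. The half-cycle cosine has zero velocity at
endpoints and reproduces the ideal sinusoid exactly when jitter is zero,
keeping closed-form checks available. A `lead_s` (1 s) ramp from mid-range
into the first bottom position and back after the last one models the
exerciser taking up and racking the weight and makes the set-boundary
endpoints detectable interior turning points. `gen_breath` places
raised-cosine bursts (peak 0.8, 2 s wide, over a 0.05 noise floor) per
movement cycle centred on the concentric endpoints (paced mode), at random
intervals (free), or with silenced hold intervals (holding, emulating a
Valsalva attempt). `gen_session` derives one independent random stream per
(master seed, exercise, set), so all output is bit-reproducible per seed.

What this does *not* emulate: tremor spectra and sensor dropouts of real
depth-camera tracking, within-set fatigue drift, correlated timing errors,
between-participant variance (population SDs mix between- and within-person
components that the generator's single knobs do not separate), or genuine
breath acoustics. Passing tests therefore demonstrate the correctness of
the feedback logic and the recoverability of known generating parameters,
not field performance on human recordings.

## Validation sizes and numerics

Noiseless round-trips must recover repetition counts exactly and durations
within two frame intervals (2/30 s). Statistical recovery uses 200
simulated sets (2000 repetitions, a few seconds of runtime): recovered
contraction-time means and SDs must sit within 3 standard errors of the
generating values, including a "control-like" profile with 2.17 s mean
concentric time. Endpoint-time quantization to the 30 Hz grid contributes
an SD of ≈ 0.014 s to recovered durations, an order below the jitter levels
tested. All comparisons of SD computations against oracles use two-pass
formulas at 1e−9 relative tolerance. Degenerate inputs are defined, not
special-cased: fewer than two repetitions give SD 0, an empty repetition
list gives all-zero metrics, a monotone trace has no endpoints, and an
all-silent breath recording yields a lights-off at exactly the timeout.

## Known limitations

- The vendor smoothing filter's prediction stage is an interpretation (the
  standard Holt forward extrapolation); other readings of the parameter
  string would differ in transient response, not in steady-state behaviour.
- Only the control and light/sound feedback conditions are modelled; a
  human coach's verbal feedback has no algorithmic content to implement.
- Endpoint variation is reported in mm throughout.
- The engine processes one set at a time; rest periods between sets are
  outside its scope.
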