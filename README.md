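# sonifit

An offline engine for **ambient-light and sonification feedback during paced
resistance exercise**, together with the kinematic and respiratory metrics
used to evaluate such feedback.

Resistance-training guidelines ask for a moderate, rhythmic pace (3 s lifting
/ concentric, 3 s lowering / eccentric), a full calibrated range of motion,
and continuous breathing — breath-holding under strain (the Valsalva
manoeuvre) acutely raises blood pressure, which matters for prehypertensive
exercisers. Home exercisers get none of the feedback a coach would give.
`sonifit` implements, as testable offline signal processing, the feedback
logic of a light-and-sound coaching system:

- **Kinematics** — the vertical hand position *y(t)* (mm, 30 Hz, from a depth
  camera) is smoothed with a Kinect-style jitter-clamped double-exponential
  (Holt) filter (`@smoothing 0.5 0.8 0.3 0.01 0.01`), turning points between
  lifting and lowering are detected, and repetitions with their concentric /
  eccentric contraction times and endpoint positions are extracted.
- **Reference model** — the ideal movement is the sinusoid
  `y_ref(t) = m − A·cos(2π(t − φ)/T)` with period `T = 6 s`
  (3 s up + 3 s down) and per-user calibrated midpoint `m` and amplitude
  `A`; its phase `φ` is re-anchored at every detected endpoint.
- **Sonification** — the velocity error `Δv = ẏ − ẏ_ref` is mapped linearly
  onto a pitch-transposition dial, clamped at ±1 octave: a melody spanning
  185–247 Hz can therefore range from 92.5 Hz to 494 Hz. Endpoint earcons
  signal a correct range of motion (success) or going too far (corrective);
  falling short stays silent; a distinct earcon marks the 10-repetition set.
- **Breathing light** — exhalations are detected from a microphone envelope
  by hysteresis thresholding; a triangular light pacer ramps 0→1 over 3 s
  (inhale) and 1→0 over 3 s (exhale); after 6 s without respiration the
  lights switch off to break a breath-hold.
- **Synthetic data** — seeded generators produce sinusoid-like sets with
  controllable pace jitter, range-of-motion bias/jitter, sample noise and
  breath patterns (paced / free / holding), so every pipeline stage can be
  validated against known ground truth.

The engine is strictly causal: replaying a recording produces, sample by
sample, exactly the feedback a live system would have produced.

## Worked example

```python
from collections import Counter
from sonifit import (ExerciserProfile, BreathPattern, SessionConfig,
                     gen_motion, gen_breath, run_session)

# a slightly hurried exerciser: ~2.2 s up / 2.7 s down, jittered endpoints
profile = ExerciserProfile(con_time_s=2.2, ecc_time_s=2.7, time_jitter_sd_s=0.3,
                           rom_jitter_sd_mm=12.0, noise_sd_mm=2.0, n_reps=10)
trace = gen_motion(profile, seed=42)
breath = gen_breath(BreathPattern(), trace, seed=43)
result = run_session(trace, breath, SessionConfig())

m = result.metrics
print(f"reps={m.n_reps}  concentric {m.mean_con_s:.2f} ({m.sd_con_s:.2f}) s  "
      f"eccentric {m.mean_ecc_s:.2f} ({m.sd_ecc_s:.2f}) s")
print(f"endpoint variation: con {m.sd_con_endpoint_mm:.1f} mm, "
      f"ecc {m.sd_ecc_endpoint_mm:.1f} mm   exhalations={m.exhalation_count}")
print(dict(Counter(e.kind.value for e in result.events)))
```

prints

```
reps=10  concentric 2.25 (0.25) s  eccentric 2.62 (0.22) s
endpoint variation: con 8.7 mm, ecc 10.8 mm   exhalations=10
{'earcon_success_con': 10, 'earcon_success_ecc': 9, 'earcon_set_complete': 1}
```

All ten repetitions are segmented; the recovered contraction times sit near
the generating profile (2.2 / 2.7 s) rather than the 3 s ideal, so the pitch
signal (in `result.pitch_signal`) spends most of the set above neutral. One
eccentric endpoint missed the ±20 mm calibration band from the inside, so
only 19 endpoint earcons sound — an undershoot is deliberately silent — and
the set-complete earcon fires at the tenth repetition.

The same workflow is available from the shell:

```bash
sonifit simulate --out-dir data --seed 5 --n-sets 1
sonifit run --motion data/bicep_curl_set1_motion.csv \
            --breath data/bicep_curl_set1_breath.csv --out-dir run1
sonifit summarize run1 --out summary.csv
sonifit demo-audio --run-dir run1 --out demo.wav   # optional listenable render
```

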