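"""Kinematics: smoothing, velocity, turning points, reps, set metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonifit import (
    EndpointEvent,
    InvalidInputError,
    MotionSample,
    MotionTrace,
    PhaseLabel,
    Repetition,
    SmoothingParams,
    detect_endpoints,
    estimate_velocity,
    segment_reps,
    set_metrics,
    smooth_trace,
)

from conftest import RATE_HZ, sine_trace


def make_trace(y, rate=RATE_HZ):
    y = np.asarray(y, dtype=float)
    return MotionTrace.from_arrays(np.arange(len(y)) / rate, y)


def holt_oracle(y, p: SmoothingParams):
    """Hand-iterated jitter-clamped Holt recurrence (independent of package)."""
    out = [y[0]]
    filt, trend = y[0], 0.0
    for raw in y[1:]:
        dev = raw - filt
        x = filt + dev * abs(dev) / p.jitter_radius_mm if abs(dev) <= p.jitter_radius_mm else raw
        new_filt = (1 - p.smoothing) * x + p.smoothing * (filt + trend)
        trend = p.correction * (new_filt - filt) + (1 - p.correction) * trend
        o = new_filt + p.prediction * trend
        if abs(o - raw) > p.max_deviation_radius_mm:
            o = raw + math.copysign(p.max_deviation_radius_mm, o - raw)
        out.append(o)
        filt = new_filt
    return np.array(out)


class TestSmoothTrace:
    def test_constant_signal_is_fixed_point(self):
        tr = make_trace([100.0] * 30)
        out = smooth_trace(tr, SmoothingParams())
        np.testing.assert_allclose(out.y, 100.0)

    def test_disabled_filter_passes_through(self):
        tr = make_trace(np.sin(np.arange(50) / 5) * 100)
        out = smooth_trace(tr, SmoothingParams.identity())
        np.testing.assert_allclose(out.y, tr.y)
        np.testing.assert_allclose(out.times, tr.times)

    def test_step_input_matches_hand_iterated_recurrence(self):
        y = np.concatenate([np.zeros(10), np.full(10, 50.0)])
        p = SmoothingParams()  # capture-pipeline defaults 0.5/0.8/0.3/10/10
        out = smooth_trace(make_trace(y), p)
        np.testing.assert_allclose(out.y, holt_oracle(y, p), rtol=1e-12)

    def test_output_never_departs_from_raw_beyond_clamp(self):
        rng = np.random.default_rng(3)
        y = np.cumsum(rng.normal(0, 15, 300))
        p = SmoothingParams()
        out = smooth_trace(make_trace(y), p)
        assert np.all(np.abs(out.y - y) <= p.max_deviation_radius_mm + 1e-9)

    @given(st.integers(min_value=2, max_value=40))
    @settings(deadline=None, max_examples=25)
    def test_causality_under_truncation(self, k):
        rng = np.random.default_rng(11)
        y = rng.normal(300, 40, 40)
        p = SmoothingParams()
        full = smooth_trace(make_trace(y), p).y
        head = smooth_trace(make_trace(y[:k]), p).y
        np.testing.assert_allclose(full[:k], head)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            smooth_trace(make_trace([1.0]), SmoothingParams())

    def test_non_monotone_time_rejected(self):
        with pytest.raises(InvalidInputError):
            MotionTrace.from_arrays([0.0, 0.5, 0.4], [0, 1, 2])


class TestEstimateVelocity:
    def test_linear_ramp(self):
        tr = MotionTrace.from_arrays(np.arange(30) / 30, 10.0 * np.arange(30) / 30)
        tv = estimate_velocity(tr)
        np.testing.assert_allclose(tv[:, 1], 10.0, atol=1e-9)

    def test_constant_signal_gives_zero(self):
        tv = estimate_velocity(make_trace([42.0] * 10))
        np.testing.assert_allclose(tv[:, 1], 0.0, atol=1e-9)

    def test_sinusoid_peak_speed_matches_closed_form(self):
        tr = sine_trace(amplitude=200.0, n_cycles=2)
        tv = estimate_velocity(tr)
        peak = np.abs(tv[:, 1]).max()
        assert peak == pytest.approx(math.pi * 200.0 / 3.0, rel=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_velocity(make_trace([0.0, 1.0]))


class TestDetectEndpoints:
    def brute_force_extrema(self, trace, period):
        """Per-cycle argmax/argmin over half-period windows (oracle)."""
        t, y = trace.times, trace.y
        out = []
        # scan half-cycles of the known sinusoid sin(2*pi*t/period):
        # maxima near period/4 + k*period, minima near 3*period/4 + k*period
        for k in range(int(t[-1] // period) + 1):
            for centre, is_max in ((period / 4 + k * period, True),
                                   (3 * period / 4 + k * period, False)):
                lo, hi = centre - period / 4, centre + period / 4
                m = (t >= lo) & (t <= hi)
                if not m.any() or hi > t[-1] or lo < t[0]:
                    continue
                idx = np.flatnonzero(m)
                j = idx[np.argmax(y[idx])] if is_max else idx[np.argmin(y[idx])]
                out.append((t[j], is_max))
        return out

    def test_clean_sinusoid_has_two_endpoints_per_cycle(self):
        tr = sine_trace(n_cycles=10)
        eps = detect_endpoints(tr)
        oracle = self.brute_force_extrema(tr, 6.0)
        assert len(eps) == 20
        labels = [e.phase_label for e in eps]
        assert labels[::2] == [PhaseLabel.CONCENTRIC] * 10
        assert labels[1::2] == [PhaseLabel.ECCENTRIC] * 10
        for e, (t_true, is_max) in zip(eps, oracle):
            assert (e.phase_label is PhaseLabel.CONCENTRIC) == is_max
            assert abs(e.time_s - t_true) <= 1.0 / RATE_HZ + 1e-9

    def test_monotone_ramp_yields_nothing(self):
        tr = make_trace(np.linspace(0, 500, 200))
        assert detect_endpoints(tr) == []

    def test_small_jitter_does_not_create_endpoints(self):
        tr = sine_trace(n_cycles=10, noise_sd=1.0, seed=5)
        eps = detect_endpoints(tr, min_prominence_mm=20.0)
        assert len(eps) == 20
        assert all(a.phase_label != b.phase_label for a, b in zip(eps, eps[1:]))

    def test_endpoints_are_time_sorted_and_spaced(self):
        tr = sine_trace(n_cycles=10, noise_sd=3.0, seed=2)
        eps = detect_endpoints(tr, min_half_period_s=0.5)
        times = [e.time_s for e in eps]
        assert times == sorted(times)
        assert min(np.diff(times)) >= 0.5


def _alt_endpoints(times, start=PhaseLabel.ECCENTRIC, y_low=100.0, y_high=500.0):
    out = []
    label = start
    for t in times:
        y = y_low if label is PhaseLabel.ECCENTRIC else y_high
        out.append(EndpointEvent(time_s=t, y_mm=y, phase_label=label))
        label = (PhaseLabel.CONCENTRIC if label is PhaseLabel.ECCENTRIC
                 else PhaseLabel.ECCENTRIC)
    return out


class TestSegmentReps:
    def test_21_alternating_endpoints_make_10_reps(self):
        reps = segment_reps(_alt_endpoints(np.arange(21) * 3.0))
        assert len(reps) == 10
        assert [r.index for r in reps] == list(range(1, 11))

    def test_ideal_pace_rep_durations(self):
        reps = segment_reps(_alt_endpoints([0.0, 3.0, 6.0]))
        assert len(reps) == 1
        assert reps[0].concentric_time_s == pytest.approx(3.0)
        assert reps[0].eccentric_time_s == pytest.approx(3.0)

    def test_asymmetric_durations_are_plain_deltas(self):
        (rep,) = segment_reps(_alt_endpoints([0.0, 2.0, 5.0]))
        assert rep.concentric_time_s == pytest.approx(2.0)
        assert rep.eccentric_time_s == pytest.approx(3.0)

    def test_trailing_unpaired_endpoint_dropped(self):
        reps = segment_reps(_alt_endpoints([0.0, 3.0, 6.0, 9.0]))
        assert len(reps) == 1

    def test_leading_concentric_dropped(self):
        reps = segment_reps(_alt_endpoints([0.0, 3.0, 6.0, 9.0],
                                           start=PhaseLabel.CONCENTRIC))
        assert len(reps) == 1
        assert reps[0].con_endpoint.time_s == 6.0

    def test_non_alternating_sequence_rejected(self):
        eps = _alt_endpoints([0.0, 3.0, 6.0])
        eps[1] = EndpointEvent(time_s=3.0, y_mm=500.0,
                               phase_label=PhaseLabel.ECCENTRIC)
        with pytest.raises(InvalidInputError):
            segment_reps(eps)


class TestSetMetrics:
    def test_identical_reps_have_zero_spread(self):
        reps = segment_reps(_alt_endpoints(np.arange(21) * 3.0))
        m = set_metrics(reps, exhalations=10)
        assert m.n_reps == 10
        assert m.mean_con_s == pytest.approx(3.0)
        assert m.mean_ecc_s == pytest.approx(3.0)
        assert (m.sd_con_s, m.sd_ecc_s) == (0.0, 0.0)
        assert (m.sd_con_endpoint_mm, m.sd_ecc_endpoint_mm) == (0.0, 0.0)
        assert m.exhalation_count == 10

    def test_sample_sd_of_known_endpoint_positions(self):
        eps = _alt_endpoints(np.arange(7) * 3.0)
        for ep, y in zip(eps[1::2], (400.0, 410.0, 420.0)):
            ep.y_mm = y
        m = set_metrics(segment_reps(eps))
        assert m.sd_con_endpoint_mm == pytest.approx(10.0)

    def test_empty_rep_list_gives_zero_metrics(self):
        m = set_metrics([], exhalations=3)
        assert m.n_reps == 0
        assert m.mean_con_s == m.sd_con_s == 0.0
        assert m.exhalation_count == 3

    def test_sds_match_two_pass_oracle(self):
        rng = np.random.default_rng(9)
        times = np.cumsum(rng.uniform(2.0, 4.0, 21))
        eps = _alt_endpoints(times)
        for ep in eps:
            ep.y_mm += rng.normal(0, 15)
        reps = segment_reps(eps)
        m = set_metrics(reps)

        def two_pass_sd(xs):
            mu = sum(xs) / len(xs)
            return math.sqrt(sum((x - mu) ** 2 for x in xs) / (len(xs) - 1))

        con_t = [r.concentric_time_s for r in reps]
        con_y = [r.con_endpoint.y_mm for r in reps]
        ecc_y = [r.ecc_endpoint.y_mm for r in reps]
        assert m.sd_con_s == pytest.approx(two_pass_sd(con_t), rel=1e-9)
        assert m.sd_con_endpoint_mm == pytest.approx(two_pass_sd(con_y), rel=1e-9)
        assert m.sd_ecc_endpoint_mm == pytest.approx(two_pass_sd(ecc_y), rel=1e-9)


class TestTraceInvariants:
    def test_pectoral_fly_requires_head_origin(self):
        with pytest.raises(InvalidInputError):
            MotionTrace.from_arrays([0.0, 0.1], [0.0, 1.0],
                                    exercise_kind="pectoral_fly",
                                    origin_ref="center_of_mass")
        tr = MotionTrace.from_arrays([0.0, 0.1], [0.0, 1.0],
                                     exercise_kind="pectoral_fly",
                                     origin_ref="head")
        assert tr.exercise_kind.value == "pectoral_fly"

    def test_nonfinite_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            MotionSample(0.0, float("nan"))
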