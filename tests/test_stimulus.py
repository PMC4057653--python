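"""Stimulus waveforms and the controller event timeline."""

import numpy as np
import pytest

from pupilkit.stimulus import (
    Shape,
    StimulusPattern,
    TargetEye,
    binocular_waveforms,
    build_timeline,
    generate_waveform,
)


def pattern(shape, **kw):
    defaults = dict(luminance_cd_m2=50.0, duration_s=10.0)
    if shape in (Shape.SINUSOID, Shape.TRIANGLE, Shape.RECTANGLE):
        defaults["frequency_hz"] = 0.5
    defaults.update(kw)
    return StimulusPattern(shape=shape, **defaults)


class TestGenerateWaveform:
    def test_single_pulse_sample_window(self):
        p = pattern(Shape.SINGLE_PULSE, duration_s=14.0, onset_s=2.0, pulse_width_s=10.0)
        w = generate_waveform(p, 75.0)
        assert len(w) == 1050
        nz = np.flatnonzero(w)
        assert nz[0] == 150 and nz[-1] == 899
        assert np.all(w[150:900] == 50.0)

    def test_sinusoid_five_periods_mean_half_luminance(self):
        w = generate_waveform(pattern(Shape.SINUSOID), 75.0)
        assert len(w) == 750
        assert abs(w.mean() - 25.0) < 1e-9
        # exactly 5 periods: the series repeats with period 150 samples
        np.testing.assert_allclose(w[:600], w[150:], atol=1e-9)
        assert w[0] == 0.0  # raised cosine starts dark

    @pytest.mark.parametrize("shape", list(Shape))
    def test_all_shapes_produced_within_range(self, shape):
        w = generate_waveform(pattern(shape, onset_s=1.0), 75.0)
        assert len(w) == 750
        assert w.min() >= 0.0 and w.max() <= 50.0
        assert np.all(w[: int(1.0 * 75)] == 0.0)  # dark before onset
        assert w.max() > 0.0

    def test_periodic_autocorrelation_at_one_period(self):
        for shape in (Shape.TRIANGLE, Shape.RECTANGLE):
            w = generate_waveform(pattern(shape), 100.0)
            lag = int(100.0 / 0.5)
            np.testing.assert_allclose(w[:-lag][w[:-lag] > -1], w[lag:], atol=1e-9)

    def test_pseudorandom_reproducible_and_seed_sensitive(self):
        a = generate_waveform(pattern(Shape.PSEUDORANDOM, seed=11), 75.0)
        b = generate_waveform(pattern(Shape.PSEUDORANDOM, seed=11), 75.0)
        c = generate_waveform(pattern(Shape.PSEUDORANDOM, seed=12), 75.0)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_ramps_span_full_range(self):
        up = generate_waveform(pattern(Shape.RAMP_POSITIVE), 75.0)
        down = generate_waveform(pattern(Shape.RAMP_NEGATIVE), 75.0)
        assert up[0] == 0.0 and up[-1] == pytest.approx(50.0, rel=0.01)
        assert down[0] == 50.0 and down[-1] == pytest.approx(0.0, abs=0.1)

    @pytest.mark.parametrize("lum", [0.5, 150.0])
    def test_luminance_outside_hardware_range_rejected(self, lum):
        with pytest.raises(ValueError, match="luminance"):
            pattern(Shape.SINGLE_PULSE, luminance_cd_m2=lum)

    def test_undersampled_periodic_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            generate_waveform(pattern(Shape.SINUSOID, frequency_hz=10.0), 15.0)


class TestBinocularClasses:
    def test_four_stimulation_classes_constructible(self):
        rate = 75.0
        for eye, check in [
            (TargetEye.LEFT, lambda l, r: l.max() > 0 and r.max() == 0),
            (TargetEye.RIGHT, lambda l, r: l.max() == 0 and r.max() > 0),
            (TargetEye.BOTH, lambda l, r: np.array_equal(l, r) and l.max() > 0),
            (TargetEye.ALTERNATING,
             lambda l, r: l.max() > 0 and r.max() > 0 and not np.any((l > 0) & (r > 0))),
        ]:
            p = pattern(Shape.SINGLE_PULSE, eye=eye, frequency_hz=0.5)
            left, right = binocular_waveforms(p, rate)
            assert check(left, right), eye


class TestBuildTimeline:
    def test_pulse_counts(self):
        p = pattern(Shape.SINGLE_PULSE, duration_s=14.0, onset_s=2.0,
                    pulse_width_s=10.0, eye=TargetEye.LEFT)
        tl = build_timeline([p], 75.0, 14.0)
        assert tl.n_frame_triggers == 1050
        assert len(tl.of_type("stimulus_on")) == 1
        assert len(tl.of_type("stimulus_off")) == 1

    def test_onset_snaps_to_next_trigger(self):
        p = pattern(Shape.SINGLE_PULSE, duration_s=14.0, onset_s=2.003,
                    pulse_width_s=10.0, eye=TargetEye.LEFT)
        tl = build_timeline([p], 75.0, 14.0)
        on = tl.of_type("stimulus_on")[0]
        assert on.time_s == pytest.approx(151 / 75.0, abs=1e-12)

    def test_events_time_sorted(self):
        p = pattern(Shape.SINGLE_PULSE, duration_s=10.0, onset_s=3.0, eye=TargetEye.BOTH)
        tl = build_timeline([p], 75.0, 10.0)
        times = [e.time_s for e in tl.events]
        assert times == sorted(times)

    def test_alternating_eyes_never_co_occur(self):
        p = pattern(Shape.SINGLE_PULSE, duration_s=8.0, eye=TargetEye.ALTERNATING,
                    frequency_hz=0.25)
        tl = build_timeline([p], 75.0, 8.0)
        active = {TargetEye.LEFT: [], TargetEye.RIGHT: []}
        for e in tl.events:
            if e.event == "stimulus_on":
                active[e.eye].append([e.time_s, None])
            elif e.event == "stimulus_off":
                active[e.eye][-1][1] = e.time_s
        for a0, a1 in active[TargetEye.LEFT]:
            for b0, b1 in active[TargetEye.RIGHT]:
                assert a1 <= b0 or b1 <= a0  # disjoint intervals

    def test_conflicting_same_eye_patterns_rejected(self):
        p1 = pattern(Shape.SINGLE_PULSE, duration_s=10.0, onset_s=0.0,
                     pulse_width_s=5.0, eye=TargetEye.LEFT)
        p2 = pattern(Shape.SINGLE_PULSE, duration_s=10.0, onset_s=3.0,
                     pulse_width_s=2.0, eye=TargetEye.LEFT)
        with pytest.raises(ValueError, match="conflict"):
            build_timeline([p1, p2], 75.0, 10.0)

    def test_fractional_duration_frame_count(self):
        tl = build_timeline([], 75.0, 10.01)
        assert tl.n_frame_triggers == int(np.floor(10.01 * 75.0)) + 1
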