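"""Trace assembly, demultiplexing, blink repair and unit conversion."""

import numpy as np
import pytest

from pupilkit.ellipse import PupilEllipse
from pupilkit.frames import Eye, RawFrame
from pupilkit.timeseries import (
    CalibrationScale,
    NoValidSamplesError,
    PupilTrace,
    demux_binocular,
    remove_blinks,
    to_mm,
    to_px,
)


def make_frame(index, eye=Eye.UNKNOWN, rate=150.0):
    return RawFrame(np.full((64, 64), 128, np.uint8), eye=eye,
                    timestamp_s=index / rate, frame_index=index)


def make_trace(majors, valid=None, rate=75.0, eye=Eye.LEFT):
    valid = [True] * len(majors) if valid is None else valid
    samples = []
    for k, (m, ok) in enumerate(zip(majors, valid)):
        if ok:
            e = PupilEllipse(center=(100.0, 100.0), orientation_rad=0.0,
                             major_axis_px=float(m), minor_axis_px=float(m) * 0.9)
        else:
            e = PupilEllipse.invalid("blink")
        samples.append((k / rate, e))
    return PupilTrace.from_ellipses(eye, samples, sampling_rate_hz=rate)


class TestDemux:
    def test_alternating_labels_split_3_3(self):
        frames = [make_frame(i, Eye.LEFT if i % 2 == 0 else Eye.RIGHT) for i in range(6)]
        left, right = demux_binocular(frames)
        assert len(left) == 3 and len(right) == 3
        assert all(f.eye == Eye.LEFT for f in left)

    def test_150_frames_at_150fps_gives_two_75_sample_streams(self):
        frames = [make_frame(i, Eye.LEFT if i % 2 == 0 else Eye.RIGHT) for i in range(150)]
        left, right = demux_binocular(frames)
        assert len(left) == len(right) == 75
        assert left[-1].timestamp_s < 1.0  # one second of recording per eye
        assert right[-1].timestamp_s < 1.0

    def test_parity_phase_assignment(self):
        frames = [make_frame(i) for i in range(10)]
        left, right = demux_binocular(frames, phase="even-left")
        assert [f.frame_index for f in left] == [0, 2, 4, 6, 8]
        left2, right2 = demux_binocular(frames, phase="even-right")
        assert [f.frame_index for f in left2] == [1, 3, 5, 7, 9]

    def test_unlabeled_without_phase_lists_offenders(self):
        frames = [make_frame(0, Eye.LEFT), make_frame(1), make_frame(2, Eye.RIGHT), make_frame(3)]
        with pytest.raises(ValueError, match=r"\[1, 3\]"):
            demux_binocular(frames)

    def test_conservation(self, rng):
        eyes = [Eye.LEFT, Eye.RIGHT]
        frames = [make_frame(i, eyes[int(rng.integers(2))]) for i in range(37)]
        left, right = demux_binocular(frames)
        assert len(left) + len(right) == len(frames)


class TestRemoveBlinks:
    def test_constant_trace_with_midstream_blinks_restored(self):
        valid = [True] * 10
        valid[4:7] = [False] * 3
        trace = make_trace([50.0] * 10, valid)
        out = remove_blinks(trace)
        assert out.valid.all()
        np.testing.assert_allclose(out.major_px, 50.0)

    def test_clean_trace_returned_unchanged(self):
        trace = make_trace(50.0 + np.sin(np.arange(30) / 5.0))
        out = remove_blinks(trace)
        np.testing.assert_array_equal(out.data[["major_px", "minor_px"]].to_numpy(),
                                      trace.data[["major_px", "minor_px"]].to_numpy())

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        majors = 60.0 + np.cumsum(rng.normal(0, 0.05, 80))
        valid = rng.random(80) > 0.15
        trace = make_trace(majors, list(valid))
        once = remove_blinks(trace)
        twice = remove_blinks(once)
        np.testing.assert_array_equal(once.data["major_px"].to_numpy(),
                                      twice.data["major_px"].to_numpy())

    def test_outlier_sample_repaired(self):
        majors = [50.0] * 20
        majors[10] = 80.0  # blink half-closure slipped past segmentation
        out = remove_blinks(make_trace(majors))
        assert out.data.loc[10, "major_px"] == pytest.approx(50.0)

    def test_leading_gap_uses_nearest_valid(self):
        valid = [False, False] + [True] * 8
        out = remove_blinks(make_trace([40.0] * 10, valid))
        assert out.data.loc[0, "major_px"] == pytest.approx(40.0)

    def test_all_invalid_raises(self):
        with pytest.raises(NoValidSamplesError):
            remove_blinks(make_trace([50.0] * 5, [False] * 5))

    def test_scripted_blinks_rmse_below_2_percent_of_baseline(self):
        """Simulator ground truth: repaired trace tracks the blink-free one."""
        from pupilkit.plr import PLRModelParams, simulate_diameter
        from pupilkit.stimulus import Shape, StimulusPattern, generate_waveform

        rate = 75.0
        pattern = StimulusPattern(shape=Shape.SINGLE_PULSE, luminance_cd_m2=50,
                                  duration_s=8.0, onset_s=2.0, pulse_width_s=3.0)
        lum = generate_waveform(pattern, rate)
        params = PLRModelParams(baseline_diameter_px=300.0, seed=1)
        truth, _ = simulate_diameter(params, lum, lum, rate)
        valid = np.ones(len(truth), bool)
        for onset in (1.0, 4.5):  # two 200-ms blinks
            k0 = int(onset * rate)
            valid[k0 : k0 + 15] = False
        trace = make_trace(truth, list(valid), rate=rate)
        out = remove_blinks(trace)
        rmse = np.sqrt(np.mean((out.major_px - truth) ** 2))
        assert rmse < 0.02 * params.baseline_diameter_px


class TestUnitConversion:
    def test_printed_phantom_scale_gives_mm_size(self):
        trace = make_trace([271.0] * 4)
        mm = to_mm(trace, CalibrationScale(3.01 / 271.0))
        assert mm.unit == "mm"
        assert round(float(mm.major_px[0]), 2) == 3.01

    def test_scale_one_is_identity_on_values(self):
        trace = make_trace([100.0, 101.0])
        mm = to_mm(trace, CalibrationScale(1.0))
        np.testing.assert_array_equal(mm.major_px, trace.major_px)

    def test_roundtrip_bit_identical(self):
        trace = make_trace(np.linspace(95, 105, 17))
        back = to_px(to_mm(trace, CalibrationScale(0.0111)))
        for c in ("center_x", "center_y", "major_px", "minor_px"):
            np.testing.assert_array_equal(back.data[c].to_numpy(), trace.data[c].to_numpy())

    def test_missing_scale_errors(self):
        with pytest.raises(ValueError, match="scale"):
            to_mm(make_trace([100.0]))

    def test_rate_above_75_rejected(self):
        with pytest.raises(ValueError, match="75"):
            make_trace([100.0], rate=80.0)
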