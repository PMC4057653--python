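"""Light-stimulus programming and the binocular event timeline.

The stimulator drives one LED per eye; each eye's program is a
:class:`StimulusPattern` — a shape (single pulse, sinusoid, triangle,
rectangle, positive/negative ramp, or a seeded pseudorandom staircase),
a luminance amplitude in cd/m^2 (hardware range 1–100), an onset relative
to the start of the recording, and a color channel.  Patterns are sampled
into luminance waveforms, and a set of patterns plus the camera frame
rate yields an :class:`EventTimeline`: frame triggers at the exact frame
period with stimulus on/off events snapped to trigger edges, mirroring
the controller, where the stimulus control pulse rides on the trigger's
rising edge.

Four binocular stimulation classes are expressible through the pattern's
``eye`` field: left only, right only, both simultaneously, and
alternating between the eyes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Shape",
    "Color",
    "TargetEye",
    "StimulusPattern",
    "TimelineEvent",
    "EventTimeline",
    "generate_waveform",
    "binocular_waveforms",
    "build_timeline",
]

LUMINANCE_RANGE = (1.0, 100.0)  # cd/m^2, stimulator hardware range


class Shape(str, enum.Enum):
    SINGLE_PULSE = "single_pulse"
    SINUSOID = "sinusoid"
    TRIANGLE = "triangle"
    RECTANGLE = "rectangle"
    RAMP_POSITIVE = "ramp_positive"
    RAMP_NEGATIVE = "ramp_negative"
    PSEUDORANDOM = "pseudorandom"


PERIODIC_SHAPES = {Shape.SINUSOID, Shape.TRIANGLE, Shape.RECTANGLE}


class Color(str, enum.Enum):
    """LED channel; colored channels have the listed peak wavelengths."""

    WHITE = "white"
    RED = "red"  # 625 nm
    GREEN = "green"  # 520 nm
    BLUE = "blue"  # 470 nm


#: Peak wavelength (nm) of the colored LED channels.
PEAK_WAVELENGTH_NM = {Color.RED: 625, Color.GREEN: 520, Color.BLUE: 470}


class TargetEye(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"
    ALTERNATING = "alternating"


@dataclass
class StimulusPattern:
    """One light-stimulus program.

    ``duration_s`` is the total program length (the sampled series covers
    ``[0, duration_s)``); the waveform is dark before ``onset_s``.  For a
    single pulse, ``pulse_width_s`` sets the lit interval (default: to the
    end of the program).  ``frequency_hz`` applies to periodic shapes and
    to the eye-alternation period of ``TargetEye.ALTERNATING``;
    ``hold_s`` is the level-hold interval of the pseudorandom staircase,
    whose levels are drawn uniformly in ``[0, luminance]`` from ``seed``.
    """

    shape: Shape
    luminance_cd_m2: float
    duration_s: float
    eye: TargetEye = TargetEye.BOTH
    color: Color = Color.WHITE
    frequency_hz: float | None = None
    onset_s: float = 0.0
    pulse_width_s: float | None = None
    hold_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = Shape(self.shape)
        self.eye = TargetEye(self.eye)
        self.color = Color(self.color)
        lo, hi = LUMINANCE_RANGE
        if not lo <= self.luminance_cd_m2 <= hi:
            raise ValueError(
                f"luminance must be within [{lo}, {hi}] cd/m^2, got {self.luminance_cd_m2}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.onset_s < 0 or self.onset_s >= self.duration_s:
            raise ValueError("onset must lie within [0, duration)")
        if self.shape in PERIODIC_SHAPES:
            if not self.frequency_hz or self.frequency_hz <= 0:
                raise ValueError(f"{self.shape.value} requires a positive frequency")
        if self.shape is Shape.PSEUDORANDOM and self.hold_s <= 0:
            raise ValueError("pseudorandom hold interval must be positive")

    @property
    def offset_s(self) -> float:
        """Time the stimulus turns off."""
        if self.shape is Shape.SINGLE_PULSE and self.pulse_width_s is not None:
            return min(self.onset_s + self.pulse_width_s, self.duration_s)
        return self.duration_s


def generate_waveform(pattern: StimulusPattern, sample_rate_hz: float) -> np.ndarray:
    """Sample a pattern into a luminance series.

    Samples at ``t_k = k / rate`` for ``k in [0, round(duration * rate))``.
    Values are zero before onset and always within ``[0, luminance]``.
    Periodic shapes span the full ``[0, luminance]`` range (the sinusoid is
    a raised cosine starting dark).  Requires ``rate >= 2 * frequency`` for
    periodic shapes.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample rate must be positive")
    if pattern.shape in PERIODIC_SHAPES and sample_rate_hz < 2 * pattern.frequency_hz:
        raise ValueError("sample rate must be at least twice the stimulus frequency")
    n = int(round(pattern.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    lum = pattern.luminance_cd_m2
    tp = t - pattern.onset_s
    active = tp >= 0
    out = np.zeros(n)
    span = pattern.duration_s - pattern.onset_s

    if pattern.shape is Shape.SINGLE_PULSE:
        width = pattern.pulse_width_s if pattern.pulse_width_s is not None else span
        out[active & (tp < width)] = lum
    elif pattern.shape is Shape.SINUSOID:
        out[active] = lum / 2.0 * (1.0 - np.cos(2.0 * np.pi * pattern.frequency_hz * tp[active]))
    elif pattern.shape is Shape.TRIANGLE:
        frac = (pattern.frequency_hz * tp[active]) % 1.0
        out[active] = lum * (2.0 * np.minimum(frac, 1.0 - frac))
    elif pattern.shape is Shape.RECTANGLE:
        frac = (pattern.frequency_hz * tp[active]) % 1.0
        out[active] = lum * (frac < 0.5)
    elif pattern.shape is Shape.RAMP_POSITIVE:
        out[active] = lum * tp[active] / span
    elif pattern.shape is Shape.RAMP_NEGATIVE:
        out[active] = lum * (1.0 - tp[active] / span)
    elif pattern.shape is Shape.PSEUDORANDOM:
        n_levels = math.ceil(span / pattern.hold_s)
        levels = np.random.default_rng(pattern.seed).uniform(0.0, lum, n_levels)
        idx = np.minimum((tp[active] / pattern.hold_s).astype(int), n_levels - 1)
        out[active] = levels[idx]
    return out


def binocular_waveforms(
    pattern: StimulusPattern, sample_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-eye (left, right) luminance series for a pattern.

    ``BOTH`` copies the waveform to both eyes; ``ALTERNATING`` gates the
    waveform between the eyes with a 50 % duty square alternation at
    ``frequency_hz`` (default 0.5 Hz when unset), starting with the left
    eye; the single-eye targets leave the fellow eye dark.
    """
    wave = generate_waveform(pattern, sample_rate_hz)
    zeros = np.zeros_like(wave)
    if pattern.eye is TargetEye.LEFT:
        return wave, zeros
    if pattern.eye is TargetEye.RIGHT:
        return zeros, wave
    if pattern.eye is TargetEye.BOTH:
        return wave, wave.copy()
    # alternating
    f = pattern.frequency_hz or 0.5
    n = len(wave)
    t = np.arange(n) / sample_rate_hz - pattern.onset_s
    left_gate = ((f * np.maximum(t, 0.0)) % 1.0) < 0.5
    return np.where(left_gate, wave, 0.0), np.where(left_gate, 0.0, wave)


@dataclass(frozen=True)
class TimelineEvent:
    time_s: float
    event: str  # frame_trigger | stimulus_on | stimulus_off | sync_pulse
    eye: TargetEye | None = None


@dataclass
class EventTimeline:
    """Time-sorted controller events for one recording."""

    events: list[TimelineEvent]
    frame_rate_hz: float
    duration_s: float

    def of_type(self, kind: str) -> list[TimelineEvent]:
        return [e for e in self.events if e.event == kind]

    @property
    def n_frame_triggers(self) -> int:
        return sum(1 for e in self.events if e.event == "frame_trigger")


def _snap_at_or_after(t: float, frame_rate_hz: float) -> float:
    """First frame-trigger time at or after ``t``."""
    k = math.ceil(t * frame_rate_hz - 1e-9)
    return k / frame_rate_hz


def build_timeline(
    patterns: list[StimulusPattern],
    frame_rate_hz: float,
    duration_s: float,
    sync_pulse: bool = True,
) -> EventTimeline:
    """Merge patterns into the controller's trigger/stimulus schedule.

    Frame triggers fire at ``k / frame_rate_hz`` over the half-open
    recording interval ``[0, duration_s)``.  Each stimulus onset/offset is
    snapped to the nearest trigger at or after its requested time (the
    control pulse rides the trigger's rising edge).  A sync pulse at t=0
    marks the master clock for co-recorded instruments.

    Raises ``ValueError`` when two patterns address the same eye over
    overlapping (snapped) intervals.
    """
    if frame_rate_hz <= 0 or duration_s <= 0:
        raise ValueError("frame rate and duration must be positive")
    n_frames = math.ceil(duration_s * frame_rate_hz - 1e-9)
    events: list[TimelineEvent] = []
    if sync_pulse:
        events.append(TimelineEvent(0.0, "sync_pulse"))
    events.extend(
        TimelineEvent(k / frame_rate_hz, "frame_trigger") for k in range(n_frames)
    )

    intervals: dict[TargetEye, list[tuple[float, float]]] = {
        TargetEye.LEFT: [],
        TargetEye.RIGHT: [],
    }
    def claim(eye: TargetEye, t_on: float, t_off: float) -> None:
        for a, b in intervals[eye]:
            if t_on < b and a < t_off:
                raise ValueError(
                    f"conflicting patterns on {eye.value} eye over"
                    f" [{max(t_on, a):g}, {min(t_off, b):g}] s"
                )
        intervals[eye].append((t_on, t_off))
        events.append(TimelineEvent(t_on, "stimulus_on", eye))
        events.append(TimelineEvent(t_off, "stimulus_off", eye))

    for p in patterns:
        t_on = _snap_at_or_after(p.onset_s, frame_rate_hz)
        t_off = min(_snap_at_or_after(p.offset_s, frame_rate_hz), duration_s)
        if p.eye is TargetEye.ALTERNATING:
            # expand into disjoint left/right half-period segments
            half_period = 1.0 / (2.0 * (p.frequency_hz or 0.5))
            m = 0
            while True:
                s = p.onset_s + m * half_period
                if s >= p.offset_s:
                    break
                seg_on = _snap_at_or_after(s, frame_rate_hz)
                seg_off = min(
                    _snap_at_or_after(min(s + half_period, p.offset_s), frame_rate_hz),
                    duration_s,
                )
                if seg_off > seg_on:
                    claim(TargetEye.LEFT if m % 2 == 0 else TargetEye.RIGHT, seg_on, seg_off)
                m += 1
        elif p.eye is TargetEye.BOTH:
            claim(TargetEye.LEFT, t_on, t_off)
            claim(TargetEye.RIGHT, t_on, t_off)
        else:
            claim(p.eye, t_on, t_off)

    events.sort(key=lambda e: (e.time_s, e.event != "sync_pulse"))
    return EventTimeline(events=events, frame_rate_hz=frame_rate_hz, duration_s=duration_s)


# -- serialization --------------------------------------------------------


def pattern_to_dict(p: StimulusPattern) -> dict:
    return {
        "shape": p.shape.value,
        "luminance_cd_m2": p.luminance_cd_m2,
        "duration_s": p.duration_s,
        "eye": p.eye.value,
        "color": p.color.value,
        "frequency_hz": p.frequency_hz,
        "onset_s": p.onset_s,
        "pulse_width_s": p.pulse_width_s,
        "hold_s": p.hold_s,
        "seed": p.seed,
    }


def pattern_from_dict(d: dict) -> StimulusPattern:
    unknown = set(d) - {f for f in StimulusPattern.__dataclass_fields__}
    if unknown:
        raise ValueError(f"unknown StimulusPattern keys: {sorted(unknown)}")
    return StimulusPattern(**d)
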