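"""Synthetic pupil-light-reflex eye videos with ground truth.

The simulator provides what no phantom can: *dynamic* binocular pupil
behavior with a known answer.  Pupil diameter follows a first-order
relaxation toward a luminance-dependent target with a pure latency, with
separate constriction and redilation time constants; the light reflex is
consensual, so the fellow eye expresses a configurable fraction of the
direct response.  Band-limited noise models hippus (spontaneous pupil
fluctuations).  This is a deliberately minimal test-fixture model — it
reproduces the qualitative shape of real pupillograms (latency, fast
constriction, slower redilation, consensual coupling, hippus) without any
claim of physiological fidelity.

Given a scripted diameter series, :func:`render_eye_video` draws
ground-truthed IR-like frames (dark pupil, faint iris, bright
background, optional corneal reflection spot) and renders blinks as
full-lid occlusion, so the entire measurement pipeline can be exercised
end-to-end and judged against the script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import Eye, RawFrame
from .phantom import AcquisitionModel

__all__ = [
    "PLRModelParams",
    "EyeLayout",
    "simulate_diameter",
    "render_eye_video",
]


@dataclass
class PLRModelParams:
    """Parameters of the two-eye pupil dynamics model.

    Sizes are in pixels at the instrument scale (about 90 px/mm), so the
    default 300 px baseline is a mid-mydriasis ~3.3 mm pupil.
    ``constriction_gain`` is the fractional diameter loss per decade of
    luminance; ``consensual_gain`` scales how much of one eye's drive
    reaches the fellow eye (1 = fully consensual).  ``hippus_amplitude_px``
    is the standard deviation of the band-limited spontaneous fluctuation
    shared by both eyes, confined to ``hippus_band_hz``.
    """

    baseline_diameter_px: float = 300.0
    constriction_gain: float = 0.15
    latency_s: float = 0.25
    tau_constrict_s: float = 0.4
    tau_redilate_s: float = 1.2
    consensual_gain: float = 0.9
    hippus_amplitude_px: float = 0.0
    hippus_band_hz: tuple[float, float] = (0.05, 0.5)
    blink_schedule: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_diameter_px <= 0:
            raise ValueError("baseline diameter must be positive")
        if not 0.0 <= self.consensual_gain <= 1.0:
            raise ValueError("consensual gain must be within [0, 1]")
        if self.tau_constrict_s <= 0 or self.tau_redilate_s <= 0:
            raise ValueError("time constants must be positive")
        if self.latency_s < 0 or self.hippus_amplitude_px < 0:
            raise ValueError("latency and hippus amplitude must be >= 0")


def _band_limited_noise(
    n: int, rate_hz: float, band: tuple[float, float], sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise band-passed to ``band`` and scaled to ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _delayed_drive(lum: np.ndarray, rate_hz: float, latency_s: float) -> np.ndarray:
    """log10(1 + luminance), delayed by the reflex latency (dark before)."""
    shift = int(round(latency_s * rate_hz))
    delayed = np.zeros_like(lum, dtype=float)
    if shift < len(lum):
        delayed[shift:] = lum[: len(lum) - shift] if shift else lum
    return np.log10(1.0 + delayed)


def simulate_diameter(
    params: PLRModelParams,
    stimulus_left: np.ndarray,
    stimulus_right: np.ndarray | None = None,
    rate_hz: float = 75.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth pupil diameter series for both eyes.

    Each eye relaxes toward a target diameter
    ``baseline * (1 - gain * u_eff)`` where the effective drive
    ``u_eff = u_own + consensual_gain * u_fellow`` combines the eye's own
    delayed log-luminance with the fellow eye's.  The step is an
    exponential (exact for piecewise-constant drive), using the
    constriction time constant when the target is below the current
    diameter and the redilation constant otherwise.  Deterministic given
    ``params.seed``.

    Returns ``(left, right)`` diameter arrays in pixels.
    """
    lum_l = np.asarray(stimulus_left, float)
    lum_r = lum_l.copy() if stimulus_right is None else np.asarray(stimulus_right, float)
    if lum_l.shape != lum_r.shape:
        raise ValueError("left and right stimulus series must have equal length")
    n = len(lum_l)
    u_l = _delayed_drive(lum_l, rate_hz, params.latency_s)
    u_r = _delayed_drive(lum_r, rate_hz, params.latency_s)
    g = params.consensual_gain
    eff_l = u_l + g * u_r
    eff_r = u_r + g * u_l

    dt = 1.0 / rate_hz
    base = params.baseline_diameter_px
    out = np.empty((2, n))
    for row, eff in enumerate((eff_l, eff_r)):
        target = base * (1.0 - params.constriction_gain * eff)
        d = base
        for k in range(n):
            tau = params.tau_constrict_s if target[k] < d else params.tau_redilate_s
            d = target[k] + (d - target[k]) * np.exp(-dt / tau)
            out[row, k] = d
    if params.hippus_amplitude_px > 0:
        rng = np.random.default_rng(params.seed)
        hip = _band_limited_noise(
            n, rate_hz, params.hippus_band_hz, params.hippus_amplitude_px, rng
        )
        out += hip  # shared fluctuation, consistent with consensual physiology
    return out[0], out[1]


@dataclass
class EyeLayout:
    """Rendering geometry for one synthetic eye.

    IR-like contrast: dark pupil on a faint iris against a bright field.
    The iris is kept close to the background intensity so that the mean
    intensity threshold isolates the pupil as the only dark object — the
    contrast regime the instrument's illumination is set up to produce.
    """

    image_size: tuple[int, int] = (256, 256)  # (width, height)
    pupil_center: tuple[float, float] | None = None
    iris_diameter_px: float | None = None
    pupil_intensity: int = 10
    iris_intensity: int = 235
    background_intensity: int = 255
    lid_intensity: int = 240
    reflection_radius_px: float = 0.0
    reflection_intensity: int = 255

    def __post_init__(self) -> None:
        if self.pupil_center is None:
            self.pupil_center = (self.image_size[0] / 2.0, self.image_size[1] / 2.0)


def render_eye_video(
    diameters: np.ndarray,
    layout: EyeLayout | None = None,
    model: AcquisitionModel | None = None,
    rate_hz: float = 75.0,
    eye: Eye = Eye.UNKNOWN,
    blink_schedule: list[tuple[float, float]] | None = None,
) -> list[RawFrame]:
    """Render a scripted diameter series as a synthetic eye video.

    Each frame draws a circular pupil of the scripted diameter (pixel-
    center rasterization, as for phantoms), an optional iris disk and
    corneal reflection spot, then applies the acquisition noise model.
    Frames falling inside a blink interval are rendered as eyelid
    occlusion: a uniform bright lid with no pupil.

    Raises ``ValueError`` if any diameter does not fit inside the frame.
    """
    layout = layout or EyeLayout()
    diam = np.asarray(diameters, float)
    w, h = layout.image_size
    cx, cy = layout.pupil_center
    max_d = float(diam.max())
    if cx - max_d / 2 < 0 or cx + max_d / 2 > w or cy - max_d / 2 < 0 or cy + max_d / 2 > h:
        raise ValueError("pupil exceeds frame bounds for the scripted diameters")
    if diam.min() <= 0:
        raise ValueError("diameters must be positive")

    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    r2 = dy2[:, None] + dx2[None, :]

    iris_mask = None
    if layout.iris_diameter_px:
        iris_mask = r2 <= (layout.iris_diameter_px / 2.0) ** 2
    spot_mask = None
    if layout.reflection_radius_px > 0:
        spot_mask = r2 <= layout.reflection_radius_px**2

    blink_schedule = blink_schedule if blink_schedule is not None else []
    rng = np.random.default_rng(None if model is None else model.seed)

    frames: list[RawFrame] = []
    for k, d in enumerate(diam):
        t = k / rate_hz
        blinking = any(a <= t < a + dur for a, dur in blink_schedule)
        if blinking:
            img = np.full((h, w), layout.lid_intensity, np.float32)
        else:
            img = np.full((h, w), layout.background_intensity, np.float32)
            if iris_mask is not None:
                img[iris_mask] = layout.iris_intensity
            img[r2 <= (d / 2.0) ** 2] = layout.pupil_intensity
            if spot_mask is not None:
                img[spot_mask] = layout.reflection_intensity
        if model is not None:
            if model.blur_sigma_px > 0:
                from scipy import ndimage as ndi

                img = ndi.gaussian_filter(img, model.blur_sigma_px)
            if model.jitter_px > 0:
                from scipy import ndimage as ndi

                img = ndi.shift(img, rng.normal(0, model.jitter_px, 2), order=1, mode="nearest")
            if model.illumination_drift > 0:
                img = img + np.float32(
                    (model.illumination_drift / 2.0) * np.sin(2 * np.pi * k / max(len(diam), 2))
                )
            if model.noise_sd > 0:
                img = img + rng.normal(0, model.noise_sd, img.shape).astype(np.float32)
        np.clip(img, 0, 255, out=img)
        frames.append(
            RawFrame(np.rint(img).astype(np.uint8), eye=eye, timestamp_s=t, frame_index=k)
        )
    return frames
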