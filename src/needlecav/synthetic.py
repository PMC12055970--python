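"""Ground-truthed synthetic shadowgraphy video and hydrophone traces.

Every downstream stage of the pipeline (bubble-area estimation, needle-tip
tracking, SPL spectrogram analysis) is exercised against scenes generated
here, for which the true projected bubble areas, tip trajectories, burst times
and ringing-tone parameters are known exactly.

The generator emulates the structure of the recordings, not their physics:

* a dark needle silhouette (side-cut lancet + bevelled cannula, or front-cut
  Franseen crown) rendered as filled polygons, undergoing programmable lateral
  (y) and longitudinal (z) motion with an abrupt stop;
* transient dark elliptical bubble clouds with analytic projected areas and
  lifetimes of order 0.1–1 ms;
* hydrophone traces made of a Gaussian noise floor, band-limited broadband
  bursts at prescribed times, and exponentially decaying ringing tones in the
  10–30 kHz band, all in calibrated pascal.

Coordinates: the frame spans ``y`` (rightward, columns) and ``z`` (upward,
-rows) in millimetres, with ``z = 0`` at the bottom edge.  Intensities follow
the shadowgraphy contract: background ≈ 220, needle/bubbles ≈ 30, additive
Gaussian noise SD 5, so binarisation by Otsu's threshold is unambiguous.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
from scipy import signal
from scipy.io import wavfile
from skimage.draw import polygon as draw_polygon

from .core import (
    DEFAULT_AUDIO_FS,
    DEFAULT_EXPOSURE_S,
    DEFAULT_FRAME_RATE,
    DEFAULT_FRAME_SIZE,
    DEFAULT_PIXEL_PITCH_UM,
    AudioTrace,
    VideoSequence,
)

#: 14 G outer diameter in millimetres.
NEEDLE_OD_MM = 2.109

# ---------------------------------------------------------------------------
# Motion profiles
# ---------------------------------------------------------------------------


@dataclass
class MotionProfile:
    """Piecewise displacement of the needle, millimetres vs seconds.

    ``y_fn``/``z_fn`` are vectorised callables returning the lateral and
    longitudinal displacement (relative to the rest pose) at trigger-aligned
    times.
    """

    y_fn: Callable[[np.ndarray], np.ndarray]
    z_fn: Callable[[np.ndarray], np.ndarray]

    def y(self, t):
        return np.asarray(self.y_fn(np.asarray(t, dtype=float)), dtype=float)

    def z(self, t):
        return np.asarray(self.z_fn(np.asarray(t, dtype=float)), dtype=float)


def static_motion() -> MotionProfile:
    """Needle at rest for the whole scene."""
    zero = lambda t: np.zeros_like(t)
    return MotionProfile(zero, zero)


def _fire_z(t, fire_start, stop_time, travel_mm, accel_frac=0.2):
    """Longitudinal firing stroke: smooth start, constant speed, hard stop."""
    t = np.asarray(t, dtype=float)
    dur = stop_time - fire_start
    ta = accel_frac * dur  # acceleration phase length
    # peak speed v so that quadratic ramp + linear phase covers travel_mm
    v = travel_mm / (dur - ta / 2.0)
    z = np.zeros_like(t)
    tau = t - fire_start
    ramp = (tau > 0) & (tau <= ta)
    lin = (tau > ta) & (tau <= dur)
    done = tau > dur
    z[ramp] = -0.5 * (v / ta) * tau[ramp] ** 2
    z[lin] = -(0.5 * v * ta + v * (tau[lin] - ta))
    z[done] = -travel_mm
    return z


def _ringdown_y(t, stop_time, amp_mm, freq_hz, decay_per_s, onset_ramp_s=0.0):
    """Damped lateral flexural oscillation starting at the abrupt stop.

    With ``onset_ramp_s`` > 0 the envelope rises as sin² over that interval,
    giving a differentiable velocity (useful for parameter-recovery
    experiments); 0 keeps the physical velocity step at the stop.
    """
    t = np.asarray(t, dtype=float)
    tau = t - stop_time
    y = np.zeros_like(t)
    m = tau > 0
    env = np.exp(-decay_per_s * tau[m])
    if onset_ramp_s > 0:
        ramp = np.minimum(tau[m] / onset_ramp_s, 1.0)
        env = env * np.sin(0.5 * np.pi * ramp) ** 2
    y[m] = amp_mm * env * np.sin(2 * np.pi * freq_hz * tau[m])
    return y


def side_cut_motion(
    fire_start: float = 0.010,
    stop_time: float = 0.025,
    travel_mm: float = 2.0,
    osc_amp_mm: float = 0.6,
    osc_freq_hz: float = 2000.0,
    osc_decay_per_s: float = 900.0,
    onset_ramp_s: float = 0.0,
) -> MotionProfile:
    """Firing stroke plus strong lateral ring-down.

    The defaults give a peak lateral tip velocity 2π·f·A ≈ 7.5 m/s, inside the
    7–10 m/s band recorded for side-cut stylet tips, and an abrupt stop at
    ``stop_time`` (trigger-aligned).
    """
    return MotionProfile(
        y_fn=lambda t: _ringdown_y(
            t, stop_time, osc_amp_mm, osc_freq_hz, osc_decay_per_s, onset_ramp_s
        ),
        z_fn=lambda t: _fire_z(t, fire_start, stop_time, travel_mm),
    )


def front_cut_motion(
    fire_start: float = 0.012,
    stop_time: float = 0.026,
    travel_mm: float = 2.0,
    osc_amp_mm: float = 0.05,
    osc_freq_hz: float = 2500.0,
    osc_decay_per_s: float = 1200.0,
) -> MotionProfile:
    """Mostly longitudinal stroke with only minor lateral motion (< 1 mm)."""
    return MotionProfile(
        y_fn=lambda t: _ringdown_y(t, stop_time, osc_amp_mm, osc_freq_hz, osc_decay_per_s),
        z_fn=lambda t: _fire_z(t, fire_start, stop_time, travel_mm),
    )


# ---------------------------------------------------------------------------
# Scene description
# ---------------------------------------------------------------------------


@dataclass
class BubbleEvent:
    """One transient elliptical bubble cloud with analytic ground truth.

    The true projected area at time ``t`` is ``π·a(t)·b(t)`` while the event
    is alive (``birth_time <= t < death_time``) and zero otherwise; if the
    ellipse is clipped by the frame boundary the truth is reduced by the
    clipped fraction.
    """

    center: tuple[float, float]  # (y_mm, z_mm)
    semi_axes: tuple[float, float]  # (a_mm, b_mm) along y and z
    birth_time: float
    death_time: float

    def __post_init__(self) -> None:
        if self.death_time <= self.birth_time:
            raise ValueError("death_time must exceed birth_time")
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")

    def alive(self, t: float) -> bool:
        return self.birth_time <= t < self.death_time

    @property
    def analytic_area_mm2(self) -> float:
        a, b = self.semi_axes
        return float(np.pi * a * b)


@dataclass
class IntensityModel:
    """8-bit shadowgraphy intensity levels."""

    background: float = 220.0
    needle_level: float = 30.0
    bubble_level: float = 30.0
    noise_sd: float = 5.0


@dataclass
class SyntheticScene:
    """Full description of a synthetic shadowgraphy recording."""

    needle_geometry: str | None = "side_cut"  # 'side_cut' | 'front_cut' | None
    motion_profile: MotionProfile = field(default_factory=static_motion)
    bubble_events: list[BubbleEvent] = field(default_factory=list)
    frame_rate: float = DEFAULT_FRAME_RATE
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE
    duration_s: float = 0.03
    time_start_s: float = -0.002  # trigger-aligned time of frame 0
    intensity: IntensityModel = field(default_factory=IntensityModel)
    seed: int = 0
    supersample: int = 4
    allow_bubble_needle_overlap: bool = False
    needle_tip: tuple[float, float] = (4.8, 4.5)  # rest tip position (y, z) mm

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("frame_rate and pixel_pitch_um must be positive")
        if self.needle_geometry not in (None, "side_cut", "front_cut"):
            raise ValueError(f"unknown needle_geometry {self.needle_geometry!r}")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    @property
    def frame_mm(self) -> tuple[float, float]:
        """Physical frame size (height_mm, width_mm)."""
        h, w = self.frame_size
        p = self.pixel_pitch_um * 1e-3
        return h * p, w * p

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.duration_s * self.frame_rate))

    def frame_times(self) -> np.ndarray:
        return self.time_start_s + np.arange(self.n_frames) / self.frame_rate


# ---------------------------------------------------------------------------
# Needle silhouettes (filled-polygon approximations of the tip geometries)
# ---------------------------------------------------------------------------


def needle_polygons(
    geometry: str, tip_y: float, tip_z: float, top_z: float
) -> tuple[list[np.ndarray], dict[str, tuple[float, float]]]:
    """Polygon silhouette and named feature points for a needle geometry.

    Returns polygons as ``(N, 2)`` arrays of (y, z) mm vertices, and a dict of
    trackable feature-point positions (tip vertices) in the same coordinates.
    ``top_z`` should lie above the frame so the shaft always reaches the edge.
    """
    d = NEEDLE_OD_MM
    if geometry == "side_cut":
        ws = 1.2  # stylet width
        # lancet-point stylet: asymmetric bevel meeting at an apex
        stylet = np.array(
            [
                (tip_y - ws / 2, top_z),
                (tip_y - ws / 2, tip_z + 0.9),
                (tip_y, tip_z),
                (tip_y + ws / 2, tip_z + 1.5),
                (tip_y + ws / 2, top_z),
            ]
        )
        zc = tip_z + 2.5  # cannula bevel tip sits behind the stylet tip
        cannula = np.array(
            [
                (tip_y - d / 2, top_z),
                (tip_y - d / 2, zc),
                (tip_y + d / 2, zc + 1.0),
                (tip_y + d / 2, top_z),
            ]
        )
        feats = {
            "stylet_tip": (tip_y, tip_z),
            "cannula_tip": (tip_y - d / 2, zc),
        }
        return [stylet, cannula], feats
    if geometry == "front_cut":
        # Franseen crown: three teeth in projection
        crown = np.array(
            [
                (tip_y - d / 2, top_z),
                (tip_y - d / 2, tip_z),
                (tip_y - d / 4, tip_z + 0.8),
                (tip_y, tip_z),
                (tip_y + d / 4, tip_z + 0.8),
                (tip_y + d / 2, tip_z),
                (tip_y + d / 2, top_z),
            ]
        )
        feats = {"cannula_tip": (tip_y, tip_z)}
        return [crown], feats
    raise ValueError(f"unknown needle geometry {geometry!r}")


# ---------------------------------------------------------------------------
# Rasterisation helpers
# ---------------------------------------------------------------------------


def _mm_to_fine(y_mm, z_mm, scene: SyntheticScene):
    """Map (y, z) mm to fractional (row, col) on the supersampled grid."""
    h_mm, _ = scene.frame_mm
    p_fine = scene.pixel_pitch_um * 1e-3 / scene.supersample
    row = (h_mm - np.asarray(z_mm)) / p_fine - 0.5
    col = np.asarray(y_mm) / p_fine - 0.5
    return row, col


def mm_to_px(y_mm, z_mm, scene: SyntheticScene):
    """Map (y, z) mm to fractional (row, col) pixel coordinates."""
    h_mm, _ = scene.frame_mm
    p = scene.pixel_pitch_um * 1e-3
    return (h_mm - np.asarray(z_mm)) / p - 0.5, np.asarray(y_mm) / p - 0.5


def _accumulate_polygon(cov: np.ndarray, poly_mm: np.ndarray, scene: SyntheticScene) -> None:
    """Add the pixel coverage of one polygon into ``cov`` (coarse grid)."""
    ss = scene.supersample
    h, w = scene.frame_size
    rr, cc = _mm_to_fine(poly_mm[:, 0], poly_mm[:, 1], scene)
    # bounding box aligned to coarse pixels
    r0 = int(np.clip(np.floor((rr.min() - 1) / ss), 0, h - 1))
    r1 = int(np.clip(np.ceil((rr.max() + 1) / ss) + 1, 1, h))
    c0 = int(np.clip(np.floor((cc.min() - 1) / ss), 0, w - 1))
    c1 = int(np.clip(np.ceil((cc.max() + 1) / ss) + 1, 1, w))
    if r1 <= r0 or c1 <= c0:
        return
    fine = np.zeros(((r1 - r0) * ss, (c1 - c0) * ss), dtype=np.float32)
    pr, pc = draw_polygon(rr - r0 * ss, cc - c0 * ss, shape=fine.shape)
    fine[pr, pc] = 1.0
    block = fine.reshape(r1 - r0, ss, c1 - c0, ss).mean(axis=(1, 3))
    np.maximum(cov[r0:r1, c0:c1], block, out=cov[r0:r1, c0:c1])


def _ellipse_coverage(
    scene: SyntheticScene, center: tuple[float, float], semi_axes: tuple[float, float]
) -> tuple[np.ndarray, tuple[int, int], float]:
    """Supersampled coverage patch of an ellipse.

    Returns ``(patch, (r0, c0), in_frame_fraction)`` where the patch is the
    coarse-grid coverage inside the frame and the fraction is the rasterised
    in-frame area divided by the analytic ellipse area.
    """
    ss = scene.supersample
    h, w = scene.frame_size
    cy, cz = center
    a, b = semi_axes
    p_fine = scene.pixel_pitch_um * 1e-3 / ss
    rr, _ = _mm_to_fine(0.0, np.array([cz - b, cz + b]), scene)
    _, cc = _mm_to_fine(np.array([cy - a, cy + a]), 0.0, scene)
    r0 = int(np.floor(min(rr) / ss)) - 1
    r1 = int(np.ceil(max(rr) / ss)) + 2
    c0 = int(np.floor(min(cc) / ss)) - 1
    c1 = int(np.ceil(max(cc) / ss)) + 2
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r1c <= r0c or c1c <= c0c:
        return np.zeros((0, 0), dtype=np.float32), (0, 0), 0.0
    # fine-grid pixel centres of the clipped patch, in mm
    fr = np.arange(r0c * ss, r1c * ss)
    fc = np.arange(c0c * ss, c1c * ss)
    h_mm, _ = scene.frame_mm
    z = h_mm - (fr + 0.5) * p_fine
    y = (fc + 0.5) * p_fine
    inside = ((y[None, :] - cy) / a) ** 2 + ((z[:, None] - cz) / b) ** 2 <= 1.0
    patch = inside.astype(np.float32).reshape(r1c - r0c, ss, c1c - c0c, ss).mean(axis=(1, 3))
    clipped = r0 < 0 or c0 < 0 or r1 > h or c1 > w
    if clipped:
        in_frame = inside.sum() * p_fine**2
        frac = float(min(1.0, in_frame / (np.pi * a * b)))
    else:
        frac = 1.0
    return patch, (r0c, c0c), frac


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------


@dataclass
class VideoGroundTruth:
    """Analytic truth recorded alongside a generated video."""

    times: np.ndarray  # trigger-aligned frame times, s
    per_event_areas: np.ndarray  # (E, T) mm², analytic ellipse areas
    total_areas: np.ndarray  # (T,) mm², analytic
    rasterized_areas: np.ndarray  # (T,) mm², pixel-count truth (coverage > 1/2)
    tip_positions_mm: dict[str, np.ndarray]  # name -> (T, 2) of (y, z) mm
    tip_positions_px: dict[str, np.ndarray]  # name -> (T, 2) of (row, col)
    displacement_mm: np.ndarray  # (T, 2) of (y, z) needle displacement
    needle_pixel_count: np.ndarray  # (T,) dark needle pixels per frame

    def to_jsonable(self) -> dict:
        return {
            "times_s": self.times.tolist(),
            "per_event_areas_mm2": self.per_event_areas.tolist(),
            "total_areas_mm2": self.total_areas.tolist(),
            "rasterized_areas_mm2": self.rasterized_areas.tolist(),
            "tip_positions_mm": {k: v.tolist() for k, v in self.tip_positions_mm.items()},
            "tip_positions_px": {k: v.tolist() for k, v in self.tip_positions_px.items()},
            "displacement_mm": self.displacement_mm.tolist(),
            "needle_pixel_count": self.needle_pixel_count.tolist(),
        }


# ---------------------------------------------------------------------------
# Video generation
# ---------------------------------------------------------------------------


def _validate_events(scene: SyntheticScene) -> None:
    h_mm, w_mm = scene.frame_mm
    for i, ev in enumerate(scene.bubble_events):
        cy, cz = ev.center
        a, b = ev.semi_axes
        if cy + a <= 0 or cy - a >= w_mm or cz + b <= 0 or cz - b >= h_mm:
            raise ValueError(
                f"bubble_events[{i}] at (y={cy}, z={cz}) mm with semi-axes "
                f"({a}, {b}) mm lies fully outside the {h_mm:.2f}x{w_mm:.2f} mm frame"
            )


def generate_video(scene: SyntheticScene) -> tuple[VideoSequence, VideoGroundTruth]:
    """Render the scene into a calibrated frame stack plus its ground truth.

    Deterministic: identical scene and seed give bit-identical frames.
    Raises ``ValueError`` for a bubble placed fully outside the frame and, by
    default, when a bubble overlaps the needle silhouette (the projected-area
    estimator cannot separate the two; pass
    ``allow_bubble_needle_overlap=True`` for robustness experiments).
    """
    _validate_events(scene)
    h, w = scene.frame_size
    times = scene.frame_times()
    T = times.size
    E = len(scene.bubble_events)
    rng = np.random.default_rng(scene.seed)
    im = scene.intensity

    frames = np.empty((T, h, w), dtype=np.uint8)
    per_event = np.zeros((E, T), dtype=float)
    raster_count = np.zeros(T, dtype=np.int64)
    needle_count = np.zeros(T, dtype=np.int64)
    disp = np.zeros((T, 2), dtype=float)

    h_mm, _ = scene.frame_mm
    top_z = h_mm + 2.0

    feat_names: list[str] = []
    if scene.needle_geometry is not None:
        _, feats0 = needle_polygons(scene.needle_geometry, *scene.needle_tip, top_z)
        feat_names = list(feats0)
    tips_mm = {k: np.zeros((T, 2)) for k in feat_names}

    dy = scene.motion_profile.y(times)
    dz = scene.motion_profile.z(times)
    disp[:, 0], disp[:, 1] = dy, dz

    # the silhouette is identical for repeated displacements (rest frames,
    # settled frames), so cache rendered needle coverage by displacement
    needle_cache: dict[tuple[int, int], np.ndarray] = {}
    ellipse_cache: dict[int, tuple[np.ndarray, tuple[int, int], float]] = {}

    for k in range(T):
        if scene.needle_geometry is not None:
            ty = scene.needle_tip[0] + dy[k]
            tz = scene.needle_tip[1] + dz[k]
            key = (round(dy[k] * 1e7), round(dz[k] * 1e7))
            if key in needle_cache:
                needle_cov = needle_cache[key]
                _, feats = needle_polygons(scene.needle_geometry, ty, tz, top_z)
            else:
                needle_cov = np.zeros((h, w), dtype=np.float32)
                polys, feats = needle_polygons(scene.needle_geometry, ty, tz, top_z)
                for poly in polys:
                    _accumulate_polygon(needle_cov, poly, scene)
                needle_cache[key] = needle_cov
            for name, pos in feats.items():
                tips_mm[name][k] = pos
        else:
            needle_cov = np.zeros((h, w), dtype=np.float32)
        needle_count[k] = int((needle_cov > 0.5).sum())

        bubble_cov = np.zeros((h, w), dtype=np.float32)
        for i, ev in enumerate(scene.bubble_events):
            if not ev.alive(times[k]):
                continue
            if i in ellipse_cache:
                patch, (r0, c0), frac = ellipse_cache[i]
            else:
                patch, (r0, c0), frac = _ellipse_coverage(scene, ev.center, ev.semi_axes)
                ellipse_cache[i] = (patch, (r0, c0), frac)
            if patch.size == 0 or frac == 0.0:
                continue
            sl = (slice(r0, r0 + patch.shape[0]), slice(c0, c0 + patch.shape[1]))
            if not scene.allow_bubble_needle_overlap:
                if np.any((patch >= 0.5) & (needle_cov[sl] >= 0.5)):
                    raise ValueError(
                        f"bubble_events[{i}] overlaps the needle silhouette at "
                        f"t={times[k]:.6f} s; move the event or set "
                        "allow_bubble_needle_overlap=True"
                    )
            np.maximum(bubble_cov[sl], patch, out=bubble_cov[sl])
            per_event[i, k] = ev.analytic_area_mm2 * frac
        raster_count[k] = int((bubble_cov > 0.5).sum())

        img = (
            im.background
            + (im.needle_level - im.background) * needle_cov
            + (im.bubble_level - im.background) * bubble_cov
        )
        np.clip(img, min(im.needle_level, im.bubble_level), im.background, out=img)
        if im.noise_sd > 0:
            img = img + rng.normal(0.0, im.noise_sd, size=img.shape)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    video = VideoSequence(
        frames=frames,
        frame_rate=scene.frame_rate,
        pixel_pitch_um=scene.pixel_pitch_um,
        exposure_s=DEFAULT_EXPOSURE_S,
        time_offset_s=scene.time_start_s,
    )
    tips_px = {}
    for name, arr in tips_mm.items():
        r, c = mm_to_px(arr[:, 0], arr[:, 1], scene)
        tips_px[name] = np.stack([r, c], axis=1)
    pitch_mm2 = (scene.pixel_pitch_um * 1e-3) ** 2
    truth = VideoGroundTruth(
        times=times,
        per_event_areas=per_event,
        total_areas=per_event.sum(axis=0),
        rasterized_areas=raster_count * pitch_mm2,
        tip_positions_mm=tips_mm,
        tip_positions_px=tips_px,
        displacement_mm=disp,
        needle_pixel_count=needle_count,
    )
    return video, truth


# ---------------------------------------------------------------------------
# Audio generation
# ---------------------------------------------------------------------------


@dataclass
class ToneSpec:
    """Exponentially decaying ringing tone: A·exp(-d·τ)·sin(2π f τ)."""

    frequency_hz: float
    decay_per_s: float
    amplitude_pa: float
    onset_s: float = 0.0


@dataclass
class SyntheticAudioSpec:
    """Hydrophone-trace recipe: noise floor + broadband bursts + ringing."""

    burst_times: Sequence[float] = ()
    burst_rms_pa: float = 5.0
    burst_duration_s: float = 0.8e-3
    burst_band_hz: tuple[float, float] = (1_000.0, 45_000.0)
    ringing_tones: Sequence[ToneSpec | tuple] = ()
    noise_floor_rms_pa: float = 0.05
    fs: float = DEFAULT_AUDIO_FS
    duration_s: float = 0.1
    trigger_index: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.ringing_tones = [
            t if isinstance(t, ToneSpec) else ToneSpec(*t) for t in self.ringing_tones
        ]
        n = int(round(self.duration_s * self.fs))
        if not 0 <= self.trigger_index < n:
            raise ValueError("trigger_index must lie within the trace")
        for tone in self.ringing_tones:
            if tone.frequency_hz >= self.fs / 2:
                raise ValueError(
                    f"tone frequency {tone.frequency_hz} Hz is not below fs/2"
                )
        if self.burst_band_hz[1] >= self.fs / 2 or self.burst_band_hz[0] <= 0:
            raise ValueError("burst band must lie strictly inside (0, fs/2)")


def generate_audio(spec: SyntheticAudioSpec) -> AudioTrace:
    """Synthesise the calibrated pressure trace described by ``spec``.

    Deterministic for a fixed seed.  Bursts are Hann-windowed band-limited
    Gaussian noise scaled so the RMS over the burst window equals
    ``burst_rms_pa``; tones are decaying sinusoids from their onset.
    """
    n = int(round(spec.duration_s * spec.fs))
    rng = np.random.default_rng(spec.seed)
    t = (np.arange(n) - spec.trigger_index) / spec.fs

    x = np.zeros(n, dtype=float)
    if spec.noise_floor_rms_pa > 0:
        x += spec.noise_floor_rms_pa * rng.standard_normal(n)

    nb = int(round(spec.burst_duration_s * spec.fs))
    if nb >= 4 and spec.burst_times:
        sos = signal.butter(
            4, spec.burst_band_hz, btype="bandpass", fs=spec.fs, output="sos"
        )
        env = signal.windows.hann(nb)
        for bt in spec.burst_times:
            j0 = int(round(bt * spec.fs)) + spec.trigger_index - nb // 2
            noise = signal.sosfiltfilt(sos, rng.standard_normal(nb + 200))[100:-100]
            burst = env * noise
            rms = np.sqrt(np.mean(burst**2))
            if rms > 0:
                burst *= spec.burst_rms_pa / rms
            a, b = max(j0, 0), min(j0 + nb, n)
            if a < b:
                x[a:b] += burst[a - j0 : b - j0]

    for tone in spec.ringing_tones:
        tau = t - tone.onset_s
        m = tau >= 0
        x[m] += (
            tone.amplitude_pa
            * np.exp(-tone.decay_per_s * tau[m])
            * np.sin(2 * np.pi * tone.frequency_hz * tau[m])
        )

    return AudioTrace(samples=x, fs=spec.fs, trigger_index=spec.trigger_index)


# ---------------------------------------------------------------------------
# Default study-condition fixtures
# ---------------------------------------------------------------------------


def default_side_cut_scene(seed: int = 0, **overrides) -> SyntheticScene:
    """Side-cut firing in water: strong lateral ring-down, bubble ensemble
    peaking at ≈3.5 mm² and lasting ≈0.84 ms after the 0.025 s stop."""
    t0 = 0.0251
    events = [
        BubbleEvent((3.4, 1.4), (0.42, 0.72), t0, t0 + 0.84e-3),
        BubbleEvent((5.0, 1.1), (0.40, 0.68), t0, t0 + 0.70e-3),
        BubbleEvent((6.6, 1.5), (0.38, 0.64), t0, t0 + 0.55e-3),
        BubbleEvent((8.0, 1.0), (0.42, 0.707), t0, t0 + 0.40e-3),
    ]
    kw = dict(
        needle_geometry="side_cut",
        motion_profile=side_cut_motion(),
        bubble_events=events,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticScene(**kw)


def default_front_cut_scene(seed: int = 0, **overrides) -> SyntheticScene:
    """Front-cut firing in water: longitudinal stop at 0.026 s triggering a
    short-lived (≈0.25 ms) small bubble pair (≈0.5 mm² peak)."""
    t0 = 0.0261
    events = [
        BubbleEvent((3.9, 1.6), (0.28, 0.30), t0, t0 + 0.25e-3),
        BubbleEvent((5.7, 1.5), (0.25, 0.30), t0, t0 + 0.20e-3),
    ]
    kw = dict(
        needle_geometry="front_cut",
        motion_profile=front_cut_motion(),
        bubble_events=events,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticScene(**kw)


def default_agarose_scene(seed: int = 0, **overrides) -> SyntheticScene:
    """1.0% w/v agarose-like condition: same firing, no bubbles (cavitation
    essentially eliminated in the stiff gel)."""
    return default_side_cut_scene(seed=seed, bubble_events=[], **overrides)


def default_side_cut_audio(seed: int = 0, **overrides) -> SyntheticAudioSpec:
    """Three broadband bursts (0.015/0.020/0.025 s) plus 10–30 kHz ringing."""
    kw = dict(
        burst_times=(0.015, 0.020, 0.025),
        burst_rms_pa=5.0,
        ringing_tones=[
            ToneSpec(12_500.0, 40.0, 2.0, onset_s=0.025),
            ToneSpec(25_000.0, 60.0, 0.8, onset_s=0.025),
        ],
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticAudioSpec(**kw)


def default_front_cut_audio(seed: int = 0, **overrides) -> SyntheticAudioSpec:
    """Two broadband bursts (0.020/0.025 s), quieter, with 10–30 kHz ringing."""
    kw = dict(
        burst_times=(0.020, 0.025),
        burst_rms_pa=2.5,
        ringing_tones=[
            ToneSpec(20_000.0, 40.0, 1.0, onset_s=0.025),
            ToneSpec(15_000.0, 60.0, 0.5, onset_s=0.025),
        ],
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticAudioSpec(**kw)


# ---------------------------------------------------------------------------
# Fixture bundles on disk
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    scene: SyntheticScene, spec: SyntheticAudioSpec, out_dir: str | Path
) -> dict:
    """Write a TIFF stack, a float WAV (pascal) and the ground-truth JSON.

    Returns the manifest (also written to ``manifest.json``) listing the three
    payload files with SHA-256 checksums and the seeds used.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    video, truth = generate_video(scene)
    trace = generate_audio(spec)

    tif_path = out / "video.tif"
    wav_path = out / "audio.wav"
    gt_path = out / "ground_truth.json"

    tifffile.imwrite(tif_path, video.frames, photometric="minisblack")
    wavfile.write(wav_path, int(spec.fs), trace.samples.astype(np.float32))

    gt = {
        "video": {
            "frame_rate": scene.frame_rate,
            "pixel_pitch_um": scene.pixel_pitch_um,
            "time_offset_s": scene.time_start_s,
            "frame_size": list(scene.frame_size),
            "needle_geometry": scene.needle_geometry,
            "seed": scene.seed,
        },
        "audio": {
            "fs": spec.fs,
            "trigger_index": spec.trigger_index,
            "burst_times_s": list(spec.burst_times),
            "burst_rms_pa": spec.burst_rms_pa,
            "ringing_tones": [
                {
                    "frequency_hz": tn.frequency_hz,
                    "decay_per_s": tn.decay_per_s,
                    "amplitude_pa": tn.amplitude_pa,
                    "onset_s": tn.onset_s,
                }
                for tn in spec.ringing_tones
            ],
            "noise_floor_rms_pa": spec.noise_floor_rms_pa,
            "seed": spec.seed,
        },
        "truth": truth.to_jsonable(),
    }
    gt_path.write_text(json.dumps(gt, sort_keys=True))

    manifest = {
        "files": [
            {"name": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in (tif_path, wav_path, gt_path)
        ],
        "seeds": {"video": scene.seed, "audio": spec.seed},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_fixture_bundle(out_dir: str | Path) -> tuple[VideoSequence, AudioTrace, dict]:
    """Read back a bundle written by :func:`write_fixture_bundle`."""
    out = Path(out_dir)
    gt = json.loads((out / "ground_truth.json").read_text())
    frames = tifffile.imread(out / "video.tif")
    fs_read, samples = wavfile.read(out / "audio.wav")
    video = VideoSequence(
        frames=frames,
        frame_rate=gt["video"]["frame_rate"],
        pixel_pitch_um=gt["video"]["pixel_pitch_um"],
        time_offset_s=gt["video"]["time_offset_s"],
    )
    trace = AudioTrace(
        samples=np.asarray(samples, dtype=float),
        fs=float(fs_read),
        trigger_index=gt["audio"]["trigger_index"],
    )
    return video, trace, gt
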