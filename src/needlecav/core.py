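"""Calibrated containers for the two co-registered measurement streams.

The experiment records a needle tip by high-speed shadowgraphy (backlit video:
needle and bubbles dark against a bright background) together with a hydrophone
pressure trace.  Both streams share a trigger event that defines t = 0 on a
common time axis, so every downstream quantity can be cross-referenced between
the optical and acoustic side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Optical scale of the recordings: one pixel corresponds to 25 µm.
DEFAULT_PIXEL_PITCH_UM = 25.0
#: Frame rate of the high-speed camera, frames per second.
DEFAULT_FRAME_RATE = 100_000.0
#: Exposure time of a single frame, seconds.
DEFAULT_EXPOSURE_S = 0.357e-6
#: Hydrophone sampling rate, Hz.
DEFAULT_AUDIO_FS = 100_000.0
#: Sensor resolution (rows, cols).
DEFAULT_FRAME_SIZE = (288, 384)


@dataclass
class VideoSequence:
    """Grayscale high-speed frame stack with its optical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``; 8-bit intensities (dark = object).
    frame_rate
        Frames per second (> 0).
    pixel_pitch_um
        Physical size of one pixel in micrometres (> 0).
    exposure_s
        Exposure time of a single frame in seconds.
    time_offset_s
        Trigger-aligned time of frame 0 in seconds (negative if recording
        starts before the trigger).
    """

    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    exposure_s: float = DEFAULT_EXPOSURE_S
    time_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def pixel_pitch_mm(self) -> float:
        return self.pixel_pitch_um * 1e-3

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm² (0.000625 mm² at 25 µm pitch)."""
        return self.pixel_pitch_mm**2

    @property
    def trigger_frame(self) -> float:
        """Frame index (possibly fractional) that maps to t = 0."""
        return -self.time_offset_s * self.frame_rate

    def times(self) -> np.ndarray:
        """Trigger-aligned time of each frame, seconds."""
        return self.time_offset_s + np.arange(self.n_frames) / self.frame_rate


@dataclass
class AudioTrace:
    """Calibrated hydrophone pressure series.

    ``samples`` are in pascal; ``trigger_index`` is the sample that maps to
    t = 0 on the shared time axis.
    """

    samples: np.ndarray
    fs: float = DEFAULT_AUDIO_FS
    trigger_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 <= self.trigger_index < self.samples.size:
            raise ValueError("trigger_index must lie within the trace")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Trigger-aligned time of each sample, seconds."""
        return (np.arange(self.n_samples) - self.trigger_index) / self.fs
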