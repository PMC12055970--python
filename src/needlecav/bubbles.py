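"""Projected bubble-area estimation from binarised shadowgraphy frames.

The estimator follows the recorded-image analysis chain: each frame is
binarised (dark pixels = needle + bubbles), and the bubble area is the number
of dark pixels in excess of the needle-at-rest count, converted to mm² with
the optical scale.  An optional needle-exclusion mode removes the needle as
the connected dark component touching the frame edge, which is robust to
needle motion (the literal subtraction rule counts displaced-needle pixels as
bubbles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import VideoSequence


@dataclass
class NeedleRestReference:
    """Binary mask (and dark-pixel count) of the needle at rest."""

    rest_mask: np.ndarray
    rest_dark_count: int
    threshold: float
    method: str

    def __post_init__(self) -> None:
        self.rest_mask = np.asarray(self.rest_mask, dtype=bool)
        if self.rest_dark_count != int(self.rest_mask.sum()):
            raise ValueError("rest_dark_count inconsistent with rest_mask")


@dataclass
class AreaSeries:
    """Projected bubble area vs trigger-aligned time, mm²."""

    times: np.ndarray
    areas: np.ndarray
    threshold: float | None = None
    n_clamped: int = 0  # frames where dark count fell below the rest count
    mode: str = "rest_subtraction"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape:
            raise ValueError("times and areas must have equal length")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")


@dataclass
class AreaSummary:
    max_area: float  # mm²
    time_of_max: float  # s
    duration: float  # s with area above the stated threshold
    area_threshold: float = 0.0


@dataclass
class ReplicateEnsemble:
    """Replicate area series on a common time grid (N = devices x replicates)."""

    series: Sequence[AreaSeries]
    device_ids: Sequence[str] = ()
    replicate_ids: Sequence[str] = ()

    def __post_init__(self) -> None:
        if len(self.series) < 2:
            raise ValueError("an ensemble needs at least 2 series")
        t0 = self.series[0].times
        for s in self.series[1:]:
            if s.times.shape != t0.shape or not np.allclose(s.times, t0):
                raise ValueError(
                    "series are not on a common time grid; resample before aggregating"
                )


def binarize_frame(
    frame: np.ndarray, method: str = "otsu", level: float | None = None
) -> tuple[np.ndarray, float]:
    """Binarise one grayscale frame; True marks dark (object) pixels,
    i.e. values at or below the threshold (Otsu's foreground convention).

    Returns ``(mask, threshold)``.  ``method='otsu'`` computes the threshold
    from the frame's histogram; ``method='fixed'`` uses ``level``.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if method == "otsu":
        if frame.min() == frame.max():
            raise ValueError(
                "constant-intensity frame: Otsu threshold is undefined, "
                "use method='fixed' with an explicit level"
            )
        thr = float(threshold_otsu(frame))
    elif method == "fixed":
        if level is None:
            raise ValueError("method='fixed' requires a level")
        thr = float(level)
    else:
        raise ValueError(f"unknown binarisation method {method!r}")
    return frame <= thr, thr


def build_rest_reference(
    rest_frames: Sequence[np.ndarray], method: str = "otsu", level: float | None = None
) -> NeedleRestReference:
    """Majority-vote needle mask over pre-firing (rest) frames.

    The threshold is computed once on the first rest frame (Otsu) or given
    explicitly, then held fixed — the same threshold should be reused for the
    whole sequence so the appearance of bubbles does not shift it.
    """
    rest_frames = list(rest_frames)
    if not rest_frames:
        raise ValueError("need at least one rest frame")
    _, thr = binarize_frame(rest_frames[0], method=method, level=level)
    votes = np.zeros(np.asarray(rest_frames[0]).shape, dtype=np.int64)
    for f in rest_frames:
        votes += np.asarray(f) <= thr
    mask = votes * 2 > len(rest_frames)
    return NeedleRestReference(
        rest_mask=mask, rest_dark_count=int(mask.sum()), threshold=thr, method=method
    )


def bubble_area_series(
    video: VideoSequence, ref: NeedleRestReference, threshold: float | None = None
) -> AreaSeries:
    """Rest-subtraction area estimate, frame by frame.

    area(k) = max(0, dark_count(k) - rest_dark_count) x (pixel pitch in mm)².
    Negative differences (needle partially out of frame) are clamped to zero
    and counted in ``n_clamped``.
    """
    thr = ref.threshold if threshold is None else float(threshold)
    if video.frame_shape != ref.rest_mask.shape:
        raise ValueError(
            f"video frames {video.frame_shape} and rest mask "
            f"{ref.rest_mask.shape} have mismatched shapes"
        )
    dark = (video.frames <= thr).sum(axis=(1, 2)).astype(np.int64)
    diff = dark - ref.rest_dark_count
    n_clamped = int((diff < 0).sum())
    areas = np.clip(diff, 0, None) * video.pixel_area_mm2
    return AreaSeries(
        times=video.times(), areas=areas, threshold=thr, n_clamped=n_clamped
    )


def _nonneedle_dark_count(mask: np.ndarray) -> int:
    """Dark pixels not part of a component touching the top frame edge."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0
    edge_labels = np.unique(labels[0, :])
    edge_labels = edge_labels[edge_labels > 0]
    keep = int(mask.sum())
    for lab in edge_labels:
        keep -= int((labels == lab).sum())
    return keep


def bubble_area_series_excluding_needle(
    video: VideoSequence, threshold: float
) -> AreaSeries:
    """Needle-exclusion area estimate (extension to the subtraction rule).

    Per frame, dark components connected to the top frame edge are treated as
    the needle (the shaft always enters from above) and removed; the remaining
    dark pixels are bubbles.  Unbiased under needle motion as long as bubbles
    do not touch the silhouette.
    """
    counts = np.array(
        [_nonneedle_dark_count(f <= threshold) for f in video.frames], dtype=np.int64
    )
    return AreaSeries(
        times=video.times(),
        areas=counts * video.pixel_area_mm2,
        threshold=float(threshold),
        mode="needle_exclusion",
    )


def summarize_area(series: AreaSeries, area_threshold: float = 0.0) -> AreaSummary:
    """Maximum area, its time, and total time spent above ``area_threshold``."""
    if series.areas.size == 0:
        raise ValueError("series is empty")
    if series.times.size > 1:
        dt = float(np.median(np.diff(series.times)))
    else:
        dt = 0.0
    above = series.areas > area_threshold
    imax = int(np.argmax(series.areas))
    return AreaSummary(
        max_area=float(series.areas[imax]),
        time_of_max=float(series.times[imax]),
        duration=float(above.sum() * dt),
        area_threshold=area_threshold,
    )


def aggregate_replicates(
    ensemble: ReplicateEnsemble,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD (ddof=1) across replicate series.

    Returns ``(times, mean, sd)`` on the common grid.
    """
    stack = np.stack([s.areas for s in ensemble.series], axis=0)
    return (
        ensemble.series[0].times.copy(),
        stack.mean(axis=0),
        stack.std(axis=0, ddof=1),
    )


def max_bubble_distance_mm(
    bubble_mask: np.ndarray, needle_mask: np.ndarray, pixel_pitch_um: float
) -> float:
    """Largest distance (mm) from any bubble pixel to the needle silhouette.

    Euclidean distance transform of the needle-free region, evaluated at
    bubble pixels.  Returns 0 if either mask is empty.
    """
    bubble_mask = np.asarray(bubble_mask, dtype=bool)
    needle_mask = np.asarray(needle_mask, dtype=bool)
    if not bubble_mask.any() or not needle_mask.any():
        return 0.0
    dist_px = ndimage.distance_transform_edt(~needle_mask)
    return float(dist_px[bubble_mask].max() * pixel_pitch_um * 1e-3)
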