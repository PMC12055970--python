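"""Calibrated SPL spectrograms and acoustic-event extraction.

The hydrophone trace (pascal) is converted to a sound pressure level
spectrogram referenced to 1 µPa via a short-time Fourier transform with a
2560-sample window and 2500-sample overlap (39.0625 Hz bins, 0.6 ms hop at
100 kHz).  Two scaling conventions are offered:

* ``'band'`` (default): power-spectrum scaling, so a bin-centred pure tone's
  peak bin reads the tone's true band SPL, 20·log10(p_rms/1 µPa), with the
  window's coherent gain compensated;
* ``'density'``: power-spectral-density scaling (levels differ by
  10·log10(ENBW)); summing bins times the bin width recovers the time-domain
  power (Parseval).

Broadband bursts are time bins where a large fraction of frequency bins rise
above their running median; persistent narrowband ridges (needle ringing) are
frequency bins that stay above the per-time median background for longer
than a persistence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import AudioTrace

#: Underwater SPL reference pressure, Pa.
P_REF = 1e-6
#: Sentinel SPL for zero-power bins, below any physical level here.
FLOOR_DB = -20.0


def band_spl(segment: np.ndarray) -> float:
    """SPL (dB re 1 µPa) of a pressure segment: 20·log10(rms / 1 µPa)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("segment is empty")
    rms = float(np.sqrt(np.mean(segment**2)))
    if rms == 0.0:
        return FLOOR_DB
    return 20.0 * np.log10(rms / P_REF)


@dataclass
class SPLSpectrogram:
    """Trigger-aligned SPL matrix (freq x time) with its STFT parameters."""

    times: np.ndarray  # s, trigger-aligned window centres
    freqs: np.ndarray  # Hz, 0..fs/2
    spl: np.ndarray  # (F, T) dB re 1 µPa
    window_size: int
    overlap: int
    window_function: str
    convention: str
    floor_db: float = FLOOR_DB

    @property
    def hop(self) -> int:
        return self.window_size - self.overlap

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BurstEvent:
    """A broadband spike in the spectrogram."""

    time: float  # s
    peak_spl: float  # dB re 1 µPa
    peak_frequency: float  # Hz
    bandwidth_fraction: float  # fraction of bins above the rise threshold


@dataclass
class ToneRidge:
    """A persistent narrowband component (needle ringing)."""

    frequency: float  # Hz
    onset: float  # s
    persistence: float  # s
    mean_spl: float  # dB re 1 µPa


def spl_spectrogram(
    trace: AudioTrace,
    window_size: int = 2560,
    overlap: int = 2500,
    window_function: str = "hann",
    convention: str = "band",
) -> SPLSpectrogram:
    """Short-time SPL spectrogram of a hydrophone trace.

    Time bins are offset so the trigger sample maps to t = 0.  Zero-power
    bins map to the documented floor.
    """
    if trace.n_samples < window_size:
        raise ValueError(
            f"trace of {trace.n_samples} samples is shorter than the "
            f"{window_size}-sample analysis window"
        )
    if not 0 < window_size - overlap:
        raise ValueError("overlap must be smaller than window_size")
    if convention not in ("band", "density"):
        raise ValueError(f"unknown convention {convention!r}")
    win = signal.get_window(window_function, window_size)
    freqs, t, sxx = signal.spectrogram(
        trace.samples,
        fs=trace.fs,
        window=win,
        nperseg=window_size,
        noverlap=overlap,
        detrend=False,
        scaling="spectrum" if convention == "band" else "density",
        mode="psd",
    )
    times = t - trace.trigger_index / trace.fs
    with np.errstate(divide="ignore"):
        spl = np.where(sxx > 0, 10.0 * np.log10(sxx / P_REF**2), FLOOR_DB)
    return SPLSpectrogram(
        times=times,
        freqs=freqs,
        spl=spl,
        window_size=window_size,
        overlap=overlap,
        window_function=window_function,
        convention=convention,
    )


def burst_detection_spectrogram(
    trace: AudioTrace, window_size: int = 512, overlap: int = 448
) -> SPLSpectrogram:
    """Short-window spectrogram for burst timing.

    The display/calibration window (2560 samples, 25.6 ms) smears millisecond
    bursts a few ms apart into a single broadband plateau; a 5.12 ms window
    resolves them while keeping enough frequency bins (Δf ≈ 195 Hz) for the
    bandwidth criterion.
    """
    return spl_spectrogram(trace, window_size=window_size, overlap=overlap)


def detect_bursts(
    spec: SPLSpectrogram,
    bandwidth_fraction_min: float = 0.5,
    spl_rise_db: float = 12.0,
    median_window_bins: int = 201,
) -> list[BurstEvent]:
    """Broadband bursts: bins where most frequencies rise above background.

    A time bin qualifies when at least ``bandwidth_fraction_min`` of the
    frequency bins exceed their per-frequency running median (window
    ``median_window_bins`` time bins) by ``spl_rise_db``.  Adjacent
    qualifying bins merge into one event, timed at the peak of the median
    broadband excess.  Use :func:`burst_detection_spectrogram` to build a
    spectrogram whose window is short enough to separate bursts a few
    milliseconds apart.
    """
    bg = ndimage.median_filter(spec.spl, size=(1, median_window_bins), mode="nearest")
    rise = spec.spl - bg
    frac = (rise > spl_rise_db).mean(axis=0)
    score = np.median(rise, axis=0)
    qual = frac >= bandwidth_fraction_min

    events: list[BurstEvent] = []
    t = spec.times
    i = 0
    n = qual.size
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qual[j + 1]:
            j += 1
        k = i + int(np.argmax(score[i : j + 1]))
        fi = int(np.argmax(spec.spl[:, k]))
        events.append(
            BurstEvent(
                time=float(t[k]),
                peak_spl=float(spec.spl[fi, k]),
                peak_frequency=float(spec.freqs[fi]),
                bandwidth_fraction=float(frac[k]),
            )
        )
        i = j + 1
    events.sort(key=lambda e: e.time)
    return events


def detect_tone_ridges(
    spec: SPLSpectrogram,
    band: tuple[float, float] = (10_000.0, 30_000.0),
    min_persistence: float = 0.02,
    rise_db: float = 10.0,
) -> list[ToneRidge]:
    """Persistent narrowband ridges within ``band``.

    The background for each time bin is the median SPL across all
    frequencies (robust to narrowband tones); a frequency bin inside the
    band forms a ridge when its SPL exceeds that background by ``rise_db``
    for at least ``min_persistence`` seconds.  Adjacent qualifying bins with
    overlapping runs merge into one ridge reported at its strongest bin.
    """
    lo, hi = band
    if not (0 <= lo < hi <= spec.freqs[-1] + spec.df):
        raise ValueError("band must lie within [0, fs/2]")
    sel = np.flatnonzero((spec.freqs >= lo) & (spec.freqs <= hi))
    if sel.size == 0:
        return []
    bg_t = np.median(spec.spl, axis=0)
    excess = spec.spl[sel] - bg_t[None, :]
    qual = excess > rise_db
    # hop duration in seconds: hop samples / fs, with fs = df * window_size
    hop_t = spec.hop / (spec.df * spec.window_size)

    # longest qualifying run per frequency bin
    candidates = []  # (sel_idx, start_bin, run_len)
    for row_idx, row in enumerate(qual):
        best_len, best_start = 0, -1
        i = 0
        while i < row.size:
            if not row[i]:
                i += 1
                continue
            j = i
            while j + 1 < row.size and row[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len, best_start = j - i + 1, i
            i = j + 1
        if best_len * hop_t >= min_persistence:
            candidates.append((row_idx, best_start, best_len))

    if not candidates:
        return []
    # merge adjacent frequency bins into ridges
    ridges: list[ToneRidge] = []
    group: list[tuple[int, int, int]] = []

    def _flush(g):
        if not g:
            return
        # strongest member bin by mean SPL over its run
        def mean_spl_of(c):
            ri, s, ln = c
            return float(spec.spl[sel[ri], s : s + ln].mean())

        best = max(g, key=mean_spl_of)
        ri, s, ln = best
        ridges.append(
            ToneRidge(
                frequency=float(spec.freqs[sel[ri]]),
                onset=float(spec.times[s]),
                persistence=float(ln * hop_t),
                mean_spl=mean_spl_of(best),
            )
        )

    for c in candidates:
        if group and c[0] - group[-1][0] > 2:
            _flush(group)
            group = []
        group.append(c)
    _flush(group)
    ridges.sort(key=lambda r: r.frequency)
    return ridges


def peak_spl(spec: SPLSpectrogram) -> tuple[float, float, float]:
    """Global maximum of the spectrogram: (spl_db, time_s, frequency_hz)."""
    fi, ti = np.unravel_index(np.argmax(spec.spl), spec.spl.shape)
    return float(spec.spl[fi, ti]), float(spec.times[ti]), float(spec.freqs[fi])
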