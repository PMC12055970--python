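"""Co-registration of video and audio, and the combined experiment report.

Both measurement streams carry a trigger reference defining t = 0 on a shared
time axis (frame k at (k - k_trigger)/frame_rate, sample j at
(j - j_trigger)/fs).  ``run_pipeline`` composes the whole analysis: bubble
area series (literal rest-subtraction and needle-exclusion modes), needle-tip
KLT kinematics with motion events, SPL spectrogram summary (peak level,
broadband bursts, ringing ridges) and the hydrodynamic numbers Ca and Re
evaluated at the measured peak lateral velocity with the medium's fluid
constants.  The report is deterministic given inputs and configuration and
serialises to a flat JSON summary plus per-series CSV files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustics import (
    burst_detection_spectrogram,
    detect_bursts,
    detect_tone_ridges,
    peak_spl,
    spl_spectrogram,
)
from .bubbles import (
    bubble_area_series,
    bubble_area_series_excluding_needle,
    build_rest_reference,
    summarize_area,
)
from .core import AudioTrace, VideoSequence
from .hydro import (
    NEEDLE_OD_M,
    FlowParameters,
    cavitation_number,
    flow_regime,
    reynolds_number,
)
from .tracking import detect_features, detect_motion_events, kinematics, track_klt

logger = logging.getLogger("needlecav")

#: Fluid constants per medium.  Water at 20 °C from standard tables; the
#: agarose kinematic viscosities are package choices anchored to a reported
#: 5e-6 m²/s for a 0.9% w/v gel (applied to the 1.0% medium, with 2e-6 m²/s
#: interpolated for 0.3%).
MEDIUM_FLUIDS: dict[str, dict[str, float]] = {
    "water": {"rho": 998.0, "mu": 1.0e-3},
    "agarose_0.3": {"rho": 1004.0, "mu": 2.0e-6 * 1004.0},
    "agarose_1.0": {"rho": 1010.0, "mu": 5.0e-6 * 1010.0},
}


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the stage name prefixes the message."""


@dataclass
class ExperimentRecord:
    """One co-registered recording: video + audio + experiment labels."""

    video: VideoSequence
    audio: AudioTrace
    needle_type: str = "side_cut"  # 'side_cut' | 'front_cut'
    medium: str = "water"  # 'water' | 'agarose_0.3' | 'agarose_1.0' | 'custom'
    metadata: dict = field(default_factory=dict)


@dataclass
class TimeAxes:
    """Trigger-aligned time axes of both streams."""

    frame_times: np.ndarray
    sample_times: np.ndarray


def coregister(video: VideoSequence, audio: AudioTrace) -> TimeAxes:
    """Shared trigger-aligned axes; t = 0 coincides across streams exactly."""
    if video.time_offset_s is None or audio.trigger_index is None:
        raise ValueError("both streams must carry a trigger reference")
    return TimeAxes(frame_times=video.times(), sample_times=audio.times())


@dataclass
class PipelineConfig:
    """All thresholds and parameters of a pipeline run (hashed for provenance)."""

    n_rest_frames: int = 50
    binarize_method: str = "otsu"
    fixed_level: float | None = None
    area_threshold_mm2: float = 0.0
    n_features: int = 2
    klt_pyramid_levels: int = 3
    klt_window: int = 15
    klt_max_iter: int = 30
    klt_tol: float = 0.01
    smoothing_frames: int = 5
    velocity_threshold_ms: float = 5.5
    spec_window: int = 2560
    spec_overlap: int = 2500
    spec_window_function: str = "hann"
    burst_bandwidth_fraction_min: float = 0.5
    burst_spl_rise_db: float = 12.0
    burst_spec_window: int = 512
    burst_spec_overlap: int = 448
    ridge_band_hz: tuple[float, float] = (10_000.0, 30_000.0)
    ridge_min_persistence_s: float = 0.02
    characteristic_length_m: float = NEEDLE_OD_M
    custom_fluid: dict | None = None

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d["ridge_band_hz"] = list(d["ridge_band_hz"])
        return json.dumps(d, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class Report:
    """Combined experiment report; every number carries units in its key."""

    needle_type: str
    medium: str
    area_literal: dict
    area_excluded: dict
    kinematics: dict
    acoustics: dict
    hydro: dict
    provenance: dict
    series: dict = field(default_factory=dict, repr=False)  # name -> DataFrame

    def to_dict(self) -> dict:
        return {
            "needle_type": self.needle_type,
            "medium": self.medium,
            "area_literal": self.area_literal,
            "area_excluded": self.area_excluded,
            "kinematics": self.kinematics,
            "acoustics": self.acoustics,
            "hydro": self.hydro,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        for name, df in self.series.items():
            df.to_csv(out / f"{name}.csv", index=False)


def _auto_tip_roi(rest_mask: np.ndarray, pad: int = 24) -> tuple[int, int, int, int]:
    """ROI around the lowest point of the needle silhouette (the tip)."""
    rows = np.flatnonzero(rest_mask.any(axis=1))
    if rows.size == 0:
        raise ValueError("rest mask contains no needle pixels")
    tip_row = rows.max()
    band = rest_mask[max(0, tip_row - pad) : tip_row + 1]
    cols = np.flatnonzero(band.any(axis=0))
    h, w = rest_mask.shape
    return (
        max(0, tip_row - 2 * pad),
        min(h, tip_row + pad),
        max(0, cols.min() - pad),
        min(w, cols.max() + pad),
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineStageError(f"{name}: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(
    record: ExperimentRecord, config: PipelineConfig | None = None
) -> Report:
    """Run the full analysis on one co-registered experiment record."""
    cfg = config or PipelineConfig()
    video, audio = record.video, record.audio
    coregister(video, audio)  # validates trigger references

    @_stage("bubble_quant")
    def _areas():
        rest = [video.frames[k] for k in range(min(cfg.n_rest_frames, video.n_frames))]
        ref = build_rest_reference(rest, method=cfg.binarize_method, level=cfg.fixed_level)
        literal = bubble_area_series(video, ref)
        excluded = bubble_area_series_excluding_needle(video, threshold=ref.threshold)
        return ref, literal, excluded

    ref, literal, excluded = _areas()

    @_stage("needle_tracking")
    def _kin():
        roi = _auto_tip_roi(ref.rest_mask)
        seeds = detect_features(video.frames[0], roi=roi, max_features=cfg.n_features)
        if not seeds:
            raise ValueError("no trackable features found in the tip ROI")
        trajectories = track_klt(
            video,
            seeds,
            pyramid_levels=cfg.klt_pyramid_levels,
            window=cfg.klt_window,
            max_iter=cfg.klt_max_iter,
            tol=cfg.klt_tol,
        )
        best = max(trajectories, key=lambda tr: int(tr.valid.sum()))
        kin = kinematics(
            best,
            frame_rate=video.frame_rate,
            pixel_pitch_um=video.pixel_pitch_um,
            smoothing=cfg.smoothing_frames,
            time_offset_s=video.time_offset_s,
        )
        events = detect_motion_events(kin, v_threshold=cfg.velocity_threshold_ms)
        return kin, events

    kin, events = _kin()

    @_stage("acoustics")
    def _acou():
        spec = spl_spectrogram(
            audio,
            window_size=cfg.spec_window,
            overlap=cfg.spec_overlap,
            window_function=cfg.spec_window_function,
        )
        det_spec = burst_detection_spectrogram(
            audio, window_size=cfg.burst_spec_window, overlap=cfg.burst_spec_overlap
        )
        bursts = detect_bursts(
            det_spec,
            bandwidth_fraction_min=cfg.burst_bandwidth_fraction_min,
            spl_rise_db=cfg.burst_spl_rise_db,
        )
        ridges = detect_tone_ridges(
            spec, band=cfg.ridge_band_hz, min_persistence=cfg.ridge_min_persistence_s
        )
        return spec, bursts, ridges

    spec, bursts, ridges = _acou()

    @_stage("hydro")
    def _hydro():
        u_peak = float(np.max(np.abs(kin.vy)))
        fluid = cfg.custom_fluid or MEDIUM_FLUIDS.get(record.medium, MEDIUM_FLUIDS["water"])
        fp = FlowParameters(u=max(u_peak, 1e-12), L=cfg.characteristic_length_m, **fluid)
        re = reynolds_number(fp)
        return {
            "peak_lateral_velocity_ms": u_peak,
            "cavitation_number": cavitation_number(fp),
            "reynolds_number": re,
            "flow_regime": flow_regime(re).value,
            "rho_kgm3": fp.rho,
            "mu_pas": fp.mu,
        }

    hydro_d = _hydro()

    sum_lit = summarize_area(literal, cfg.area_threshold_mm2)
    sum_exc = summarize_area(excluded, cfg.area_threshold_mm2)
    pk_spl, pk_t, pk_f = peak_spl(spec)

    series = {
        "area_literal": pd.DataFrame(
            {"time_s": literal.times, "area_mm2": literal.areas}
        ),
        "area_excluded": pd.DataFrame(
            {"time_s": excluded.times, "area_mm2": excluded.areas}
        ),
        "kinematics": pd.DataFrame(
            {
                "time_s": kin.times,
                "y_mm": kin.y_mm,
                "z_mm": kin.z_mm,
                "vy_ms": kin.vy,
                "vz_ms": kin.vz,
                "ay_ms2": kin.ay,
                "az_ms2": kin.az,
            }
        ),
    }

    return Report(
        needle_type=record.needle_type,
        medium=record.medium,
        area_literal={
            "max_area_mm2": sum_lit.max_area,
            "time_of_max_s": sum_lit.time_of_max,
            "duration_s": sum_lit.duration,
            "n_clamped_frames": literal.n_clamped,
            "binarize_threshold": literal.threshold,
        },
        area_excluded={
            "max_area_mm2": sum_exc.max_area,
            "time_of_max_s": sum_exc.time_of_max,
            "duration_s": sum_exc.duration,
        },
        kinematics={
            "peak_lateral_velocity_ms": float(np.max(np.abs(kin.vy))),
            "peak_longitudinal_velocity_ms": float(np.max(np.abs(kin.vz))),
            "peak_acceleration_ms2": float(np.max(np.hypot(kin.ay, kin.az))),
            "stop_time_s": events.stop_time,
            "n_velocity_crossings": len(events.crossings),
            "velocity_threshold_ms": cfg.velocity_threshold_ms,
            "smoothing": kin.smoothing,
        },
        acoustics={
            "peak_spl_db_re_1upa": pk_spl,
            "peak_spl_time_s": pk_t,
            "peak_spl_frequency_hz": pk_f,
            "n_bursts": len(bursts),
            "burst_times_s": [b.time for b in bursts],
            "burst_peak_spls_db": [b.peak_spl for b in bursts],
            "n_tone_ridges": len(ridges),
            "ridge_frequencies_hz": [r.frequency for r in ridges],
        },
        hydro=hydro_d,
        provenance={
            "config_hash": cfg.hash,
            "config": json.loads(cfg.canonical_json()),
            "package_version": __version__,
        },
        series=series,
    )
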