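#!/usr/bin/env python
"""Full co-registered pipeline reports for the three study conditions:
side cut in water, front cut in water, and the 1.0% agarose-like condition
(same firing, no bubbles).  Writes one report directory per condition under
results/ with the JSON summary and the per-series CSV files."""

from pathlib import Path

import needlecav as nc
from needlecav.synthetic import side_cut_motion

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

conditions = [
    (
        "side_cut_water",
        nc.default_side_cut_scene(seed=400),
        nc.default_side_cut_audio(seed=401),
        "side_cut",
        "water",
    ),
    (
        "front_cut_water",
        nc.default_front_cut_scene(seed=402),
        nc.default_front_cut_audio(seed=403),
        "front_cut",
        "water",
    ),
    (
        "side_cut_agarose_1.0",
        nc.default_agarose_scene(seed=404),
        nc.default_side_cut_audio(seed=405, burst_times=(0.015, 0.020, 0.025)),
        "side_cut",
        "agarose_1.0",
    ),
]

for name, scene, audio_spec, needle, medium in conditions:
    video, truth = nc.generate_video(scene)
    audio = nc.generate_audio(audio_spec)
    record = nc.ExperimentRecord(
        video=video, audio=audio, needle_type=needle, medium=medium
    )
    report = nc.run_pipeline(record, nc.PipelineConfig())
    out = RESULTS / f"report_{name}"
    report.write(out)
    print(
        f"{name}: max area {report.area_excluded['max_area_mm2']:.3f} mm² "
        f"(truth {truth.total_areas.max():.3f}), "
        f"{report.acoustics['n_bursts']} bursts, "
        f"peak |vy| {report.kinematics['peak_lateral_velocity_ms']:.2f} m/s, "
        f"Ca {report.hydro['cavitation_number']:.2f}, Re {report.hydro['reynolds_number']:.0f} "
        f"-> {out}"
    )
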