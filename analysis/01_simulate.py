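#!/usr/bin/env python
"""Generate the two study-condition fixtures (side cut and front cut in
water) as on-disk bundles: TIFF stack, float-Pa WAV, ground-truth JSON and a
checksummed manifest.

Media go under scratch/fixtures/ (large, regenerable); a compact summary of
what was generated lands in results/simulate_summary.json.
"""

import json
from pathlib import Path

import needlecav as nc

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"

summary = {}
for name, scene_fn, audio_fn in [
    ("side_cut", nc.default_side_cut_scene, nc.default_side_cut_audio),
    ("front_cut", nc.default_front_cut_scene, nc.default_front_cut_audio),
]:
    scene = scene_fn(seed=100)
    spec = audio_fn(seed=101)
    out = SCRATCH / name
    manifest = nc.write_fixture_bundle(scene, spec, out)
    summary[name] = {
        "bundle": str(out.relative_to(ROOT)),
        "n_frames": scene.n_frames,
        "frame_size": list(scene.frame_size),
        "frame_rate": scene.frame_rate,
        "burst_times_s": list(spec.burst_times),
        "files": manifest["files"],
    }
    print(f"{name}: {scene.n_frames} frames + {spec.duration_s*1e3:.0f} ms audio -> {out}")

RESULTS.mkdir(exist_ok=True)
(RESULTS / "simulate_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
print(f"summary -> {RESULTS / 'simulate_summary.json'}")
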