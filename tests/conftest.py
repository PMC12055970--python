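"""Shared fixtures: a full-length side-cut experiment is expensive to render
(3000 frames at 384x288), so it is generated once per session and reused by
the pipeline and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import needlecav as nc
from needlecav.synthetic import side_cut_motion


@pytest.fixture(scope="session")
def side_cut_scene():
    """Study-condition side-cut scene; the lateral ring-down gets a short
    differentiable onset so the analytic peak velocity is recoverable after
    the default displacement smoothing."""
    return nc.default_side_cut_scene(
        seed=21, motion_profile=side_cut_motion(onset_ramp_s=0.3e-3)
    )


@pytest.fixture(scope="session")
def side_cut_experiment(side_cut_scene):
    """(video, truth, audio_spec, audio) for one full side-cut firing."""
    video, truth = nc.generate_video(side_cut_scene)
    spec = nc.default_side_cut_audio(seed=22)
    audio = nc.generate_audio(spec)
    return video, truth, spec, audio


@pytest.fixture(scope="session")
def side_cut_report(side_cut_scene, side_cut_experiment):
    video, truth, spec, audio = side_cut_experiment
    record = nc.ExperimentRecord(
        video=video, audio=audio, needle_type="side_cut", medium="water"
    )
    return nc.run_pipeline(record, nc.PipelineConfig())
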