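"""Shared fixtures: synthetic scenes and perfect-detection helpers."""

from __future__ import annotations

import pytest
from hypothesis import settings

from colonytrack.detect import Detection

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from colonytrack.synthgen import GroundTruth, SceneConfig, sample_scene


def noiseless_config(seed: int = 0, **overrides) -> SceneConfig:
    """Drift-free, noise-free default scene used by exact round-trip tests."""
    kwargs = dict(noise_sigma=0.0, drift_sigma=0.0, seed=seed)
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


def gt_as_detections(gt: GroundTruth, confidence: float = 0.99) -> list[list[Detection]]:
    """Feed ground-truth boxes through the tracker as ideal detections."""
    return [
        [Detection(e.bbox, e.label, confidence, sl) for e in gt.entries[sl]]
        for sl in range(gt.n_slices)
    ]


@pytest.fixture
def small_scene():
    cfg = noiseless_config(seed=42)
    objects, gt = sample_scene(cfg)
    return cfg, objects, gt
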