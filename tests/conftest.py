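"""Shared fixtures: synthetic scenes and datasets reused across modules.

Everything is generated in-process from fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import swarmsense as ss


@pytest.fixture(scope="session")
def clean_scene():
    """Five well-separated parallel fish, 51 steps, zero rendering noise.

    Returns (trajectory, frames, ground_truth).
    """
    cfg = ss.SwarmSimConfig(n_fish=5, steps=51, seed=7, base_heading=0.3)
    traj = ss.simulate_swarm(ss.SwarmPattern.PARALLEL, cfg)
    frames, truth = ss.render_frames(traj, ss.NoiseConfig.none(), fish_radius=5)
    return traj, frames, truth


@pytest.fixture(scope="session")
def clean_detections(clean_scene):
    _, frames, _ = clean_scene
    return ss.detect_sequence(frames)


@pytest.fixture(scope="session")
def pattern_dataset_400():
    """Balanced 400-image trajectory-image dataset (100 per pattern)."""
    return ss.make_pattern_dataset(100, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
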