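"""Shared fixtures and evaluation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import melanotrack as mt
from melanotrack.core import FLUORESCENCE, TRANSMITTED, MovieStack


def make_stack(
    transmitted: np.ndarray,
    fluorescence: list[np.ndarray] | None = None,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> MovieStack:
    """Build a MovieStack from per-channel (T, H, W) arrays."""
    fluorescence = fluorescence or []
    channels = [np.asarray(transmitted, dtype=float)] + [
        np.asarray(f, dtype=float) for f in fluorescence
    ]
    pixels = np.stack(channels, axis=1)
    roles = [TRANSMITTED] + [FLUORESCENCE] * len(fluorescence)
    return MovieStack(
        pixels=pixels, pixel_size=pixel_size, frame_interval=frame_interval, channel_roles=roles
    )


def assign_detections_to_truth(observations, truth_positions, gate=0.3):
    """Map detection index -> ground-truth particle id by gated assignment."""
    if not observations:
        return {}
    points = np.array([[o.x, o.y] for o in observations])
    dists = np.linalg.norm(points[:, None, :] - truth_positions[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(np.where(dists <= gate, dists, 1e6))
    return {int(r): int(c) for r, c in zip(rows, cols) if dists[r, c] <= gate}


def link_recovery_rate(stack, truth, detection=None, gate=1.2):
    """Fraction of ground-truth frame-to-frame links recovered by the tracker.

    A link (particle p, frame t -> t+1) counts as recovered when the tracker
    connects a detection assigned to p at t with a detection assigned to p at
    t+1.  Missed detections therefore count against recovery.
    """
    detection = detection or mt.DetectionParams()
    threshold = detection.intensity_threshold or mt.auto_threshold(stack)
    frames = mt.detect_movie(
        stack, threshold, detection.min_area, detection.max_area, detection.polarity
    )
    ids = [
        assign_detections_to_truth(frames[t], truth.positions[t])
        for t in range(truth.n_frames)
    ]
    total = truth.n_particles * (truth.n_frames - 1)
    correct = 0
    for t in range(truth.n_frames - 1):
        for i, j in mt.link_frame_pair(frames[t], frames[t + 1], gate):
            if i in ids[t] and j in ids[t + 1] and ids[t][i] == ids[t + 1][j]:
                correct += 1
    return correct / total


@pytest.fixture(scope="session")
def default_movie():
    """One default-condition synthetic movie shared across read-only tests."""
    config = mt.SimulationConfig(seed=11)
    stack, truth = mt.simulate_movie(config)
    return config, stack, truth
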