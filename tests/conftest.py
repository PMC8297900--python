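"""Shared fixtures: hand-built pose sequences and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import attachmon as am
from attachmon.kinematics import FEATURE_COLUMNS
from attachmon.pose_io import COCO18_JOINTS, Keypoint, KeypointFrame, PoseSequence


def make_sequence(
    wrist_tracks: dict[str, list[tuple[float, float, float]]],
    frame_rate: float = 30.0,
    width: int = 320,
    height: int = 240,
    child_id: str = "t0",
) -> PoseSequence:
    """Build a sequence from explicit wrist (x, y, confidence) tracks.

    All other joints sit at a fixed plausible location with confidence 0.95.
    """
    n = len(next(iter(wrist_tracks.values())))
    frames = []
    for t in range(n):
        kps = {}
        for name in COCO18_JOINTS:
            if name in wrist_tracks:
                x, y, c = wrist_tracks[name][t]
                kps[name] = Keypoint(x, y, c)
            else:
                kps[name] = Keypoint(width * 0.5, height * 0.3, 0.95)
        frames.append(KeypointFrame(frame_index=t, time=t / frame_rate, keypoints=kps))
    return PoseSequence(
        child_id=child_id,
        frame_rate=frame_rate,
        image_width=width,
        image_height=height,
        frames=frames,
    )


def make_feature_windows(
    n_per_class: int,
    window_size: int = 128,
    seed: int = 0,
    speed_gap: float = 0.5,
) -> list[am.FeatureWindow]:
    """Directly constructed, linearly separable labelled windows.

    Secure windows have near-zero speeds/accelerations; insecure windows
    have speeds elevated by ``speed_gap``.  Used as a classifier oracle
    independent of the motion simulator.
    """
    rng = np.random.default_rng(seed)
    windows = []
    for cls, label in ((0, am.AttachmentLabel.B), (1, am.AttachmentLabel.C)):
        for k in range(n_per_class):
            mat = np.zeros((window_size, len(FEATURE_COLUMNS)))
            pos = rng.uniform(0.3, 0.7, size=4)
            mat[:, 0:4] = pos + 0.01 * rng.standard_normal((window_size, 4))
            mat[:, 4] = 0.2 + 0.01 * rng.standard_normal(window_size)  # dist
            mat[:, 5] = 1.0  # dist_valid
            base_speed = 0.05 + cls * speed_gap
            mat[:, 6:8] = np.abs(
                base_speed + 0.02 * rng.standard_normal((window_size, 2))
            )
            mat[:, 8:10] = np.abs(
                base_speed * 2 + 0.05 * rng.standard_normal((window_size, 2))
            )
            mat[:, 10:12] = mat[:, [0, 2]]
            mat[:, 12:14] = 1.0
            windows.append(
                am.FeatureWindow(
                    child_id=f"cls{cls}_{k}",
                    window_index=0,
                    frames=mat,
                    left_presence_prop=1.0,
                    right_presence_prop=1.0,
                    label=label,
                )
            )
    return windows


@pytest.fixture(scope="session")
def separable_windows() -> list[am.FeatureWindow]:
    return make_feature_windows(40, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort: (sequences, labels, windows_by_child)."""
    spec = am.SyntheticCohortSpec(
        n_children=10, frames_per_child=512, secure_fraction=0.5, seed=3
    )
    sequences, labels = am.simulate_cohort(spec)
    cfg = am.FeatureConfig()
    windows = {
        s.child_id: am.sequence_windows(s, cfg, labels[s.child_id])
        for s in sequences
    }
    return sequences, labels, windows


@pytest.fixture()
def published_confusion() -> am.ConfusionMatrixK:
    from attachmon.reference import sam_mcast_confusion

    return sam_mcast_confusion()
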