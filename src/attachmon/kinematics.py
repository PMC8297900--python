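"""Per-frame kinematic features of the two hands and fixed-length windowing.

From each pose frame, six feature families are derived for the two wrist
keypoints (the hands holding the dolls):

* hand position — per-axis image-normalized coordinates x/W, y/H in [0, 1];
* distance between the hands — Euclidean distance in the normalized
  coordinates, defined only when both hands are present;
* hand speed — backward finite difference of position times the frame
  rate, in normalized units per second (speed at frame 0 is 0);
* hand acceleration — absolute backward difference of scalar speed times
  the frame rate (0 at frames 0 and 1);
* hand 1-D trajectory — the horizontal placing x/W of each hand;
* hand presence — per-frame booleans, summarized per window as the
  proportion of frames in which each hand is detected (a child moving one
  doll much more than the other shows up here).

Absent hands follow a configurable missing policy: ``hold-last`` (default)
keeps the last seen position so that dropouts do not fabricate speed
spikes, while the presence flags carry the dropout information; ``zero``
zeroes the kinematic channels instead.  The inter-hand distance when a
hand is absent holds its last defined value and is flagged invalid in a
companion column.

Feature sequences are cut into non-overlapping windows of ``window_size``
consecutive frames (default 128, about 4.25 s at 30 fps); the trailing
remainder is discarded.  Windows are the classifier's unit of decision.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .labels import AttachmentLabel
from .pose_io import PoseSequence

__all__ = [
    "FeatureConfig",
    "FeatureWindow",
    "FEATURE_COLUMNS",
    "extract_features",
    "window_features",
    "sequence_windows",
    "feature_schema_hash",
]

#: Column order of the per-frame feature matrix.
FEATURE_COLUMNS: tuple[str, ...] = (
    "left_x",
    "left_y",
    "right_x",
    "right_y",
    "dist",
    "dist_valid",
    "left_speed",
    "right_speed",
    "left_accel",
    "right_accel",
    "left_traj1d",
    "right_traj1d",
    "left_present",
    "right_present",
)

#: Channels that vary continuously (summarized by mean/std); the remaining
#: columns are 0/1 flags summarized by their window proportion.
CONTINUOUS_COLUMNS: tuple[str, ...] = (
    "left_x",
    "left_y",
    "right_x",
    "right_y",
    "dist",
    "left_speed",
    "right_speed",
    "left_accel",
    "right_accel",
    "left_traj1d",
    "right_traj1d",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction and windowing parameters."""

    window_size: int = 128
    frame_rate: float | None = None  # None: use the sequence's own rate
    missing_policy: str = "hold-last"  # or "zero"
    left_joint: str = "left_wrist"
    right_joint: str = "right_wrist"

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ConfigError("window_size must be >= 2")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.missing_policy not in ("hold-last", "zero"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class FeatureWindow:
    """``window_size`` consecutive frame-feature vectors for one child."""

    child_id: str
    window_index: int
    frames: np.ndarray  # (window_size, len(FEATURE_COLUMNS))
    left_presence_prop: float
    right_presence_prop: float
    label: AttachmentLabel | None = None
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != len(self.columns):
            raise ValueError("frames must be (window_size, n_channels)")


def feature_schema_hash(columns: Sequence[str] = FEATURE_COLUMNS) -> str:
    """Short stable hash of the feature column schema."""
    return hashlib.sha1("|".join(columns).encode()).hexdigest()[:12]


def _hand_track(
    seq: PoseSequence, joint: str, policy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (T, 2) positions under the missing policy + presence mask."""
    T = len(seq.frames)
    pos = np.zeros((T, 2))
    present = np.zeros(T, dtype=bool)
    w, h = float(seq.image_width), float(seq.image_height)
    # backfill the stretch before the first detection with the first seen
    # position so dropouts at the start do not fabricate motion
    first = np.array([0.5, 0.5])
    for fr in seq.frames:
        kp = fr.get(joint, seq.missing_threshold)
        if kp is not None:
            first = np.array([kp.x / w, kp.y / h])
            break
    last = first
    for t, fr in enumerate(seq.frames):
        kp = fr.get(joint, seq.missing_threshold)
        if kp is not None:
            last = np.array([kp.x / w, kp.y / h])
            present[t] = True
            pos[t] = last
        elif policy == "hold-last":
            pos[t] = last
        else:  # zero
            pos[t] = 0.0
    return pos, present


def extract_features(seq: PoseSequence, cfg: FeatureConfig) -> pd.DataFrame:
    """Convert a pose sequence into the per-frame feature matrix.

    Returns a DataFrame with one row per input frame and columns
    :data:`FEATURE_COLUMNS`.  Speeds use backward differences scaled by the
    frame rate, accelerations the absolute backward difference of speed;
    both are zero-padded at the sequence start.
    """
    if len(seq.frames) < 2:
        raise DegenerateInputError("need at least 2 frames for kinematics")
    if seq.image_width <= 0 or seq.image_height <= 0:
        raise ConfigError("image dimensions must be positive")
    fps = cfg.frame_rate if cfg.frame_rate is not None else seq.frame_rate

    lpos, lpres = _hand_track(seq, cfg.left_joint, cfg.missing_policy)
    rpos, rpres = _hand_track(seq, cfg.right_joint, cfg.missing_policy)

    def speed_accel(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1) * fps
        speed = np.concatenate([[0.0], d])
        a = np.abs(np.diff(speed)) * fps
        accel = np.concatenate([[0.0], a])
        accel[1] = 0.0  # speed at 0 is padding, not a measurement
        return speed, accel

    lspeed, laccel = speed_accel(lpos)
    rspeed, raccel = speed_accel(rpos)

    both = lpres & rpres
    raw_dist = np.linalg.norm(lpos - rpos, axis=1)
    dist = np.empty_like(raw_dist)
    last_valid = float(raw_dist[both.argmax()]) if both.any() else 0.0
    for t in range(len(raw_dist)):
        if both[t]:
            last_valid = raw_dist[t]
        dist[t] = last_valid

    return pd.DataFrame(
        {
            "left_x": lpos[:, 0],
            "left_y": lpos[:, 1],
            "right_x": rpos[:, 0],
            "right_y": rpos[:, 1],
            "dist": dist,
            "dist_valid": both.astype(float),
            "left_speed": lspeed,
            "right_speed": rspeed,
            "left_accel": laccel,
            "right_accel": raccel,
            "left_traj1d": lpos[:, 0],
            "right_traj1d": rpos[:, 0],
            "left_present": lpres.astype(float),
            "right_present": rpres.astype(float),
        }
    )


def window_features(
    features: pd.DataFrame,
    cfg: FeatureConfig,
    child_id: str,
    label: AttachmentLabel | None = None,
) -> list[FeatureWindow]:
    """Cut the frame-feature matrix into non-overlapping windows.

    Yields ``floor(T / window_size)`` windows; the remainder frames at the
    end are discarded.  Each window inherits the child's label and carries
    its own presence proportions.
    """
    if list(features.columns) != list(FEATURE_COLUMNS):
        raise ValueError("feature matrix columns do not match FEATURE_COLUMNS")
    T = len(features)
    W = cfg.window_size
    mat = features.to_numpy(dtype=float)
    windows = []
    for k in range(T // W):
        block = mat[k * W : (k + 1) * W]
        lcol = FEATURE_COLUMNS.index("left_present")
        rcol = FEATURE_COLUMNS.index("right_present")
        windows.append(
            FeatureWindow(
                child_id=child_id,
                window_index=k,
                frames=block,
                left_presence_prop=float(block[:, lcol].mean()),
                right_presence_prop=float(block[:, rcol].mean()),
                label=label,
            )
        )
    return windows


def sequence_windows(
    seq: PoseSequence,
    cfg: FeatureConfig,
    label: AttachmentLabel | None = None,
) -> list[FeatureWindow]:
    """Extract features from a pose sequence and window them in one step."""
    return window_features(extract_features(seq, cfg), cfg, seq.child_id, label)
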