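"""Seeded class-conditional simulator of two-hand doll-play keypoint data.

Real sessions cannot be shared, so the pipeline is exercised on simulated
pose sequences whose two wrist tracks differ between a "secure-like" and an
"insecure-like" motion regime in all six feature families the rater
consumes (position, inter-hand distance, speed, acceleration, horizontal
trajectory, presence).

Each hand follows critically damped second-order (spring–damper) dynamics
toward a piecewise-constant target — smooth, settling motion rather than a
random walk, mirroring the smooth proximity-seeking movement that
characterises secure doll play.  Targets switch at Poisson-distributed
events; half of the events start an *approach*, during which both targets
contract toward a shared point at ``approach_rate``.  Gaussian acceleration
noise (``jerk_sd``) roughens the motion, observation noise (``noise_sd``)
jitters the reported keypoints, and each hand independently drops out per
frame with its dropout probability (one-sided dropout emulates a child
moving one doll much more than the other).  Positions reflect off the
image margins so all keypoints stay inside the frame.

The secure preset has fast approaches, a small resting inter-hand
distance, little jerk and symmetric, rare dropout; the insecure preset is
a mixture family (avoidant-like: wide resting distance, one-sided dropout;
ambivalent/disorganised-like: frequent target switching, high jerk).  All
non-wrist joints are emitted as a static plausible upper-body layout with
high confidence so files are schema-complete.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .labels import AttachmentLabel
from .pose_io import COCO18_JOINTS, Keypoint, KeypointFrame, PoseSequence

__all__ = [
    "MotionClassParams",
    "SyntheticCohortSpec",
    "secure_preset",
    "insecure_preset",
    "interpolate_params",
    "simulate_child",
    "simulate_cohort",
]

#: Static fractional (x, y) layout of the non-wrist joints (face and upper
#: body fill the frame; lower-body joints sit near the bottom edge).
_STATIC_LAYOUT: dict[str, tuple[float, float]] = {
    "nose": (0.50, 0.18),
    "neck": (0.50, 0.32),
    "right_shoulder": (0.38, 0.33),
    "right_elbow": (0.30, 0.50),
    "left_shoulder": (0.62, 0.33),
    "left_elbow": (0.70, 0.50),
    "right_hip": (0.42, 0.80),
    "right_knee": (0.42, 0.92),
    "right_ankle": (0.42, 0.98),
    "left_hip": (0.58, 0.80),
    "left_knee": (0.58, 0.92),
    "left_ankle": (0.58, 0.98),
    "right_eye": (0.46, 0.15),
    "left_eye": (0.54, 0.15),
    "right_ear": (0.42, 0.17),
    "left_ear": (0.58, 0.17),
}

_MARGIN = 0.05  # reflective boundary inside the unit square
_OMEGA = 6.0  # natural frequency of the spring-damper, rad/s


@dataclass(frozen=True)
class MotionClassParams:
    """Class-conditional motion-regime parameters (normalized units)."""

    approach_rate: float  # 1/s: target contraction during approach events
    event_rate: float  # events/minute: target switching
    noise_sd: float  # positional observation jitter
    jerk_sd: float  # acceleration noise, units/s^2
    dropout_left: float  # per-frame absence probability
    dropout_right: float
    rest_distance: float  # resting inter-hand target distance

    def __post_init__(self) -> None:
        if min(self.approach_rate, self.event_rate, self.noise_sd, self.jerk_sd) < 0:
            raise ConfigError("rates and noise levels must be non-negative")
        for p in (self.dropout_left, self.dropout_right):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("dropout probabilities must be in [0, 1]")
        if not 0.0 < self.rest_distance <= 1.5:
            raise ConfigError("rest_distance must be in (0, 1.5]")


def secure_preset() -> MotionClassParams:
    """Smooth, fast proximity-seeking play with both dolls in view."""
    return MotionClassParams(
        approach_rate=2.0,
        event_rate=8.0,
        noise_sd=0.004,
        jerk_sd=0.08,
        dropout_left=0.02,
        dropout_right=0.02,
        rest_distance=0.15,
    )


def insecure_preset() -> MotionClassParams:
    """Wide-separation, jerky, one-doll-dominant play."""
    return MotionClassParams(
        approach_rate=0.25,
        event_rate=24.0,
        noise_sd=0.015,
        jerk_sd=0.9,
        dropout_left=0.03,
        dropout_right=0.28,
        rest_distance=0.45,
    )


def interpolate_params(
    a: MotionClassParams, b: MotionClassParams, t: float
) -> MotionClassParams:
    """Linear interpolation from ``a`` (t=0) to ``b`` (t=1), field by field."""
    fields = {
        f.name: (1 - t) * getattr(a, f.name) + t * getattr(b, f.name)
        for f in dataclasses.fields(MotionClassParams)
    }
    return MotionClassParams(**fields)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A simulated study cohort.

    Defaults describe the reference evaluation cohort: 40 children, half
    secure, 768 frames each (six 128-frame windows at 30 fps, ~25 s of
    play per child), a 320x240 image, and the two default class presets.
    """

    n_children: int = 40
    secure_fraction: float = 0.5
    frames_per_child: int = 768
    frame_rate: float = 30.0
    image_width: int = 320
    image_height: int = 240
    secure_params: MotionClassParams = dataclasses.field(
        default_factory=secure_preset
    )
    insecure_params: MotionClassParams = dataclasses.field(
        default_factory=insecure_preset
    )
    #: scale of the A/C/D sublabel variation around ``insecure_params``
    #: (0 = all insecure children share exactly ``insecure_params``)
    mixture_spread: float = 1.0
    seed: int = 11

    def __post_init__(self) -> None:
        if self.n_children < 2:
            raise ConfigError("n_children must be >= 2")
        if not 0.0 < self.secure_fraction < 1.0:
            raise ConfigError("secure_fraction must be in (0, 1)")
        if self.frames_per_child < 128:
            raise ConfigError(
                "frames_per_child must cover at least one 128-frame window"
            )


def simulate_child(
    params: MotionClassParams,
    n_frames: int,
    frame_rate: float = 30.0,
    image_width: int = 320,
    image_height: int = 240,
    seed: int | np.random.SeedSequence = 0,
    child_id: str = "synthetic-child",
) -> PoseSequence:
    """Simulate one child session as a schema-complete pose sequence.

    Output is a pure function of the arguments; the same seed reproduces
    the sequence bit for bit.
    """
    if n_frames < 2:
        raise DegenerateInputError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    p_event = params.event_rate / 60.0 * dt

    # the doll-placement region widens with the resting separation: children
    # who keep the dolls far apart also range wider across the image, which
    # is what the position / 1-D-trajectory families pick up
    half_w = min(0.42, 0.18 + 0.5 * params.rest_distance)
    half_h = min(0.30, 0.12 + 0.3 * params.rest_distance)

    def new_targets() -> np.ndarray:
        base = rng.uniform(
            [0.5 - half_w, 0.5 - half_h], [0.5 + half_w, 0.5 + half_h]
        )
        theta = rng.uniform(0.0, 2.0 * np.pi)
        off = 0.5 * params.rest_distance * np.array([np.cos(theta), np.sin(theta)])
        return np.clip(
            np.stack([base + off, base - off]), _MARGIN + 0.01, 1.0 - _MARGIN - 0.01
        )

    targets = new_targets()
    pos = targets.copy()  # start settled at the resting targets
    vel = np.zeros_like(pos)
    approaching = False

    frames: list[KeypointFrame] = []
    W, H = float(image_width), float(image_height)
    scale = np.array([W, H])
    for t in range(n_frames):
        if rng.random() < p_event:
            if rng.random() < 0.5:
                approaching = True
            else:
                approaching = False
                targets = new_targets()
        if approaching:
            shared = targets.mean(axis=0)
            targets = targets + params.approach_rate * (shared - targets) * dt
        accel = (
            _OMEGA**2 * (targets - pos)
            - 2.0 * _OMEGA * vel
            + params.jerk_sd * rng.standard_normal(pos.shape)
        )
        vel = vel + accel * dt
        pos = pos + vel * dt
        # reflective boundary
        for h in range(2):
            for ax in range(2):
                if pos[h, ax] < _MARGIN:
                    pos[h, ax] = 2 * _MARGIN - pos[h, ax]
                    vel[h, ax] = -vel[h, ax]
                elif pos[h, ax] > 1.0 - _MARGIN:
                    pos[h, ax] = 2 * (1.0 - _MARGIN) - pos[h, ax]
                    vel[h, ax] = -vel[h, ax]

        obs = pos + params.noise_sd * rng.standard_normal(pos.shape)
        obs = np.clip(obs, 0.0, 1.0)
        left_out = rng.random() < params.dropout_left
        right_out = rng.random() < params.dropout_right

        keypoints: dict[str, Keypoint] = {}
        for name in COCO18_JOINTS:
            if name == "left_wrist":
                keypoints[name] = (
                    Keypoint(0.0, 0.0, 0.0)
                    if left_out
                    else Keypoint(obs[0, 0] * W, obs[0, 1] * H, 0.9)
                )
            elif name == "right_wrist":
                keypoints[name] = (
                    Keypoint(0.0, 0.0, 0.0)
                    if right_out
                    else Keypoint(obs[1, 0] * W, obs[1, 1] * H, 0.9)
                )
            else:
                fx, fy = _STATIC_LAYOUT[name]
                keypoints[name] = Keypoint(fx * W, fy * H, 0.95)
        frames.append(
            KeypointFrame(frame_index=t, time=t / frame_rate, keypoints=keypoints)
        )

    return PoseSequence(
        child_id=child_id,
        frame_rate=frame_rate,
        image_width=image_width,
        image_height=image_height,
        frames=frames,
    )


def _sublabel_variant(
    base: MotionClassParams, sublabel: AttachmentLabel, spread: float
) -> MotionClassParams:
    """Mild deterministic tweaks giving the insecure mixture its sublabels.

    ``spread`` scales the deviation from ``base``; at 0 every insecure
    child shares exactly ``base`` (the strict-null configuration).
    """
    d = dataclasses.asdict(base)
    if sublabel is AttachmentLabel.A:  # avoidant: wide and one-sided
        d["rest_distance"] = min(1.5, d["rest_distance"] * (1 + 0.2 * spread))
        d["dropout_right"] = min(1.0, d["dropout_right"] * (1 + 0.3 * spread))
    elif sublabel is AttachmentLabel.C:  # ambivalent: restless switching
        d["event_rate"] = d["event_rate"] * (1 + 0.3 * spread)
    elif sublabel is AttachmentLabel.D:  # disorganised: extra jerk
        d["jerk_sd"] = d["jerk_sd"] * (1 + 0.3 * spread)
    return MotionClassParams(**d)


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[PoseSequence], dict[str, AttachmentLabel]]:
    """Simulate a labelled cohort of children.

    ``round(n_children * secure_fraction)`` children are labelled B and use
    the secure parameters; the rest split A/C/D in equal thirds (remainder
    to C) around the insecure parameters.  Child streams are spawned from
    one seed sequence, so the cohort is reproducible and children are
    statistically independent.
    """
    n_secure = round(spec.n_children * spec.secure_fraction)
    n_insecure = spec.n_children - n_secure
    q, rem = divmod(n_insecure, 3)
    sublabels = (
        [AttachmentLabel.A] * q
        + [AttachmentLabel.C] * (q + rem)
        + [AttachmentLabel.D] * q
    )
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_children)

    sequences: list[PoseSequence] = []
    labels: dict[str, AttachmentLabel] = {}
    for i in range(spec.n_children):
        cid = f"c{i:03d}"
        if i < n_secure:
            label = AttachmentLabel.B
            params = spec.secure_params
        else:
            label = sublabels[i - n_secure]
            params = _sublabel_variant(
                spec.insecure_params, label, spec.mixture_spread
            )
        sequences.append(
            simulate_child(
                params,
                n_frames=spec.frames_per_child,
                frame_rate=spec.frame_rate,
                image_width=spec.image_width,
                image_height=spec.image_height,
                seed=child_seeds[i],
                child_id=cid,
            )
        )
        labels[cid] = label
    return sequences, labels
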