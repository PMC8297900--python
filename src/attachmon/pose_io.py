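"""Reading and writing pose-keypoint sequences and attachment label tables.

A session is one child playing through the doll-play story stems in front
of a camera; a pose-estimation network reduces each video frame to a set of
2-D body keypoints with detection confidences.  This module consumes that
output in a JSON dialect compatible with the common pose-network export:
each frame record holds ``people[i]["pose_keypoints_2d"]``, a flat
``[x1, y1, c1, x2, y2, c2, ...]`` triplet list in a fixed joint order;
session metadata (child id, frame rate, image geometry, joint names) lives
in a header object.  A whole session may be one JSON file (header plus a
``frames`` array) or a directory of per-frame JSON files, concatenated in
lexicographic order, with the header in ``_header.json``.

Conventions:

* coordinates are pixels, origin top-left, x rightward, y downward;
* a keypoint with confidence below the missing threshold (default 0.1) is
  absent; confidence exactly 0 always means absent; absent keypoints are
  stored and written as ``(0, 0, 0)``;
* when a frame contains several detected people, the one with the largest
  keypoint bounding box is kept (the child is the near subject) and the
  event is logged.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import FormatError, LabelError, SchemaError
from .labels import AttachmentLabel

__all__ = [
    "COCO18_JOINTS",
    "Keypoint",
    "KeypointFrame",
    "PoseSequence",
    "read_pose_json",
    "write_pose_json",
    "read_labels",
    "write_labels",
]

logger = logging.getLogger(__name__)

#: Default 18-joint body vocabulary (COCO-style ordering).  The two wrist
#: joints stand in for the hands: the camera frames face and upper body, so
#: wrist keypoints are the tracked proxy for the dolls held in the hands.
COCO18_JOINTS: tuple[str, ...] = (
    "nose",
    "neck",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
    "right_eye",
    "left_eye",
    "right_ear",
    "left_ear",
)

DEFAULT_MISSING_THRESHOLD = 0.1


@dataclass(frozen=True)
class Keypoint:
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


ABSENT = Keypoint(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class KeypointFrame:
    """Keypoints of one video frame."""

    frame_index: int
    time: float
    keypoints: Mapping[str, Keypoint]

    def present(self, joint: str, threshold: float) -> bool:
        kp = self.keypoints.get(joint)
        if kp is None:
            return False
        return kp.confidence > 0.0 and kp.confidence >= threshold

    def get(self, joint: str, threshold: float) -> Keypoint | None:
        """The keypoint, or None if absent at the given threshold."""
        return self.keypoints[joint] if self.present(joint, threshold) else None


@dataclass
class PoseSequence:
    """An ordered keypoint sequence for one child session."""

    child_id: str
    frame_rate: float
    image_width: int
    image_height: int
    frames: list[KeypointFrame]
    joint_names: tuple[str, ...] = COCO18_JOINTS
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        last = -1
        for fr in self.frames:
            if fr.frame_index <= last:
                raise ValueError("frame_index must be strictly increasing")
            last = fr.frame_index

    def __len__(self) -> int:
        return len(self.frames)


def _frame_from_record(
    record: Mapping,
    frame_index: int,
    joint_names: Sequence[str],
    frame_rate: float,
    missing_threshold: float,
) -> KeypointFrame:
    people = record.get("people", [])
    if not isinstance(people, list):
        raise FormatError("frame record field 'people' must be a list")
    triplets: Sequence[float] | None = None
    if len(people) == 1:
        triplets = people[0].get("pose_keypoints_2d")
    elif len(people) > 1:
        # keep the person with the largest keypoint bounding box
        best_area = -1.0
        for person in people:
            t = person.get("pose_keypoints_2d", [])
            xs = [t[i] for i in range(0, len(t), 3) if t[i + 2] > 0]
            ys = [t[i + 1] for i in range(0, len(t), 3) if t[i + 2] > 0]
            area = (max(xs) - min(xs)) * (max(ys) - min(ys)) if xs else 0.0
            if area > best_area:
                best_area = area
                triplets = t
        logger.info(
            "frame %d: %d people detected; kept the largest bounding box",
            frame_index,
            len(people),
        )
    if triplets is None:
        triplets = [0.0] * (3 * len(joint_names))
    if len(triplets) != 3 * len(joint_names):
        raise SchemaError(
            f"frame {frame_index}: {len(triplets)} values, expected "
            f"{3 * len(joint_names)} for {len(joint_names)} joints"
        )
    keypoints: dict[str, Keypoint] = {}
    for j, name in enumerate(joint_names):
        x, y, c = triplets[3 * j : 3 * j + 3]
        if not 0.0 <= c <= 1.0 or not (math.isfinite(x) and math.isfinite(y)):
            raise FormatError(f"frame {frame_index}, joint {name}: bad triplet")
        if c == 0.0 or c < missing_threshold:
            keypoints[name] = ABSENT
        else:
            keypoints[name] = Keypoint(float(x), float(y), float(c))
    idx = int(record.get("frame_index", frame_index))
    time = float(record.get("time", idx / frame_rate))
    return KeypointFrame(frame_index=idx, time=time, keypoints=keypoints)


def _load_session_records(path: Path) -> tuple[dict, list]:
    """Return (header, frame records) from a file or per-frame directory."""
    if path.is_dir():
        header_path = path / "_header.json"
        if not header_path.exists():
            raise FormatError(f"per-frame directory {path} lacks _header.json")
        header = json.loads(header_path.read_text())
        records = []
        for p in sorted(path.glob("*.json")):
            if p.name == "_header.json":
                continue
            records.append(json.loads(p.read_text()))
        return header, records
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise FormatError(f"{path}: expected a header object with a 'frames' array")
    return doc, doc["frames"]


def read_pose_json(
    path: str | Path,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
) -> PoseSequence:
    """Read one session's pose sequence from a JSON file or directory.

    Keypoints with confidence below ``missing_threshold`` (or exactly 0)
    are marked absent.  The output frame count always equals the input
    frame-record count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file() and path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    header, records = _load_session_records(path)
    try:
        child_id = str(header["child_id"])
        frame_rate = float(header["frame_rate"])
        width = int(header["image_width"])
        height = int(header["image_height"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc.args[0]!r}") from exc
    joint_names = tuple(header.get("joint_names", COCO18_JOINTS))
    frames = [
        _frame_from_record(rec, i, joint_names, frame_rate, missing_threshold)
        for i, rec in enumerate(records)
    ]
    return PoseSequence(
        child_id=child_id,
        frame_rate=frame_rate,
        image_width=width,
        image_height=height,
        frames=frames,
        joint_names=joint_names,
        missing_threshold=missing_threshold,
    )


def write_pose_json(seq: PoseSequence, path: str | Path) -> None:
    """Write a session to a single JSON file; inverse of :func:`read_pose_json`.

    Absent keypoints are encoded as ``(0, 0, 0)`` triplets.
    """
    path = Path(path)
    records = []
    for fr in seq.frames:
        triplets: list[float] = []
        for name in seq.joint_names:
            kp = fr.keypoints.get(name, ABSENT)
            if not fr.present(name, seq.missing_threshold):
                kp = ABSENT
            triplets.extend([kp.x, kp.y, kp.confidence])
        records.append(
            {
                "frame_index": fr.frame_index,
                "time": fr.time,
                "people": [{"pose_keypoints_2d": triplets}],
            }
        )
    doc = {
        "child_id": seq.child_id,
        "frame_rate": seq.frame_rate,
        "image_width": seq.image_width,
        "image_height": seq.image_height,
        "joint_names": list(seq.joint_names),
        "frames": records,
    }
    path.write_text(json.dumps(doc))


def read_labels(path: str | Path) -> dict[str, AttachmentLabel]:
    """Read a ``child_id,label`` CSV into a label table.

    Raises :class:`LabelError` on an unknown code (naming the row) or a
    duplicated child id.
    """
    path = Path(path)
    table: dict[str, AttachmentLabel] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"child_id", "label"} <= set(
            reader.fieldnames
        ):
            raise FormatError(f"{path}: expected header 'child_id,label'")
        for i, row in enumerate(reader, start=2):
            cid = row["child_id"].strip()
            if cid in table:
                raise LabelError(f"{path} line {i}: duplicate child_id {cid!r}")
            try:
                table[cid] = AttachmentLabel.from_code(row["label"])
            except ValueError as exc:
                raise LabelError(f"{path} line {i}: {exc}") from exc
    return table


def write_labels(table: Mapping[str, AttachmentLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["child_id", "label"])
        for cid, label in table.items():
            writer.writerow([cid, label.value])
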