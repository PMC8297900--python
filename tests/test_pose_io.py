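"""Pose/label I/O: dialects, absence conventions, round trips."""

import json

import numpy as np
import pytest

import attachmon as am
from attachmon.errors import FormatError, LabelError, SchemaError
from attachmon.pose_io import COCO18_JOINTS, read_labels, read_pose_json, write_pose_json

from conftest import make_sequence


def _track(points):
    return [(x, y, c) for (x, y, c) in points]


def test_full_confidence_sequence_round_trips(tmp_path):
    track = [(100.0 + t, 120.0, 0.9) for t in range(10)]
    seq = make_sequence({"left_wrist": track, "right_wrist": track})
    path = tmp_path / "s.json"
    write_pose_json(seq, path)
    back = read_pose_json(path)
    assert len(back) == 10
    assert back.child_id == seq.child_id
    assert back.frame_rate == seq.frame_rate
    assert (back.image_width, back.image_height) == (320, 240)
    for fa, fb in zip(seq.frames, back.frames):
        assert fa.frame_index == fb.frame_index
        assert fa.time == fb.time
        for name in COCO18_JOINTS:
            ka, kb = fa.keypoints[name], fb.keypoints[name]
            assert (ka.x, ka.y, ka.confidence) == (kb.x, kb.y, kb.confidence)
    # no absences anywhere
    assert all(
        fb.present(n, back.missing_threshold) for fb in back.frames for n in COCO18_JOINTS
    )


def test_zero_confidence_wrist_marked_absent(tmp_path):
    track = [(0.0, 0.0, 0.0)] + [(100.0, 100.0, 0.9)] * 4
    seq = make_sequence({"left_wrist": track, "right_wrist": [(50, 50, 0.9)] * 5})
    path = tmp_path / "s.json"
    write_pose_json(seq, path)
    back = read_pose_json(path)
    assert not back.frames[0].present("left_wrist", back.missing_threshold)
    assert back.frames[1].present("left_wrist", back.missing_threshold)


def test_absences_survive_round_trip(tmp_path):
    # below-threshold confidence is normalised to (0, 0, 0) on read and write
    track = [(90.0, 90.0, 0.05)] * 3 + [(90.0, 90.0, 0.9)] * 3
    seq_path = tmp_path / "a.json"
    write_pose_json(
        make_sequence({"left_wrist": track, "right_wrist": track}), seq_path
    )
    back = read_pose_json(seq_path)
    assert back.frames[0].keypoints["left_wrist"].confidence == 0.0
    round2 = tmp_path / "b.json"
    write_pose_json(back, round2)
    assert read_pose_json(round2).frames[0].keypoints["left_wrist"].confidence == 0.0


def test_empty_frame_list_round_trips(tmp_path):
    seq = am.PoseSequence(
        child_id="e", frame_rate=30.0, image_width=64, image_height=48, frames=[]
    )
    path = tmp_path / "empty.json"
    write_pose_json(seq, path)
    back = read_pose_json(path)
    assert len(back) == 0 and back.child_id == "e"


def test_frame_count_preserved_and_synthetic_round_trip(tmp_path):
    seq = am.simulate_child(am.secure_preset(), 128, seed=42, child_id="rt")
    path = tmp_path / "rt.json"
    write_pose_json(seq, path)
    back = read_pose_json(path)
    assert len(back) == 128
    for fa, fb in zip(seq.frames, back.frames):
        for name in COCO18_JOINTS:
            ka, kb = fa.keypoints[name], fb.keypoints[name]
            present = fa.present(name, seq.missing_threshold)
            assert fb.present(name, back.missing_threshold) == present
            if present:
                assert ka.x == pytest.approx(kb.x) and ka.y == pytest.approx(kb.y)


def test_absence_monotone_in_threshold(tmp_path):
    rng = np.random.default_rng(1)
    track = [(100.0, 100.0, float(c)) for c in rng.uniform(0, 1, size=50)]
    path = tmp_path / "m.json"
    write_pose_json(make_sequence({"left_wrist": track, "right_wrist": track}), path)
    presence = {}
    for thr in (0.05, 0.3, 0.6, 0.9):
        back = read_pose_json(path, missing_threshold=thr)
        presence[thr] = [f.present("left_wrist", thr) for f in back.frames]
    thresholds = sorted(presence)
    for lo, hi in zip(thresholds, thresholds[1:]):
        for p_lo, p_hi in zip(presence[lo], presence[hi]):
            assert p_hi <= p_lo  # raising the threshold never resurrects


def test_per_frame_directory_concatenated_lexicographically(tmp_path):
    d = tmp_path / "session"
    d.mkdir()
    (d / "_header.json").write_text(
        json.dumps(
            {
                "child_id": "dirkid",
                "frame_rate": 30.0,
                "image_width": 100,
                "image_height": 100,
                "joint_names": ["left_wrist", "right_wrist"],
            }
        )
    )
    for t in range(3):
        (d / f"frame_{t:04d}.json").write_text(
            json.dumps(
                {"people": [{"pose_keypoints_2d": [10.0 * t, 5.0, 0.9, 20.0, 5.0, 0.9]}]}
            )
        )
    seq = read_pose_json(d)
    assert len(seq) == 3
    assert [f.keypoints["left_wrist"].x for f in seq.frames] == [0.0, 10.0, 20.0]


def test_multiple_people_keeps_largest_bounding_box(tmp_path):
    small = [40.0, 40.0, 0.9, 45.0, 45.0, 0.9]
    big = [10.0, 10.0, 0.9, 90.0, 90.0, 0.9]
    doc = {
        "child_id": "two",
        "frame_rate": 30.0,
        "image_width": 100,
        "image_height": 100,
        "joint_names": ["left_wrist", "right_wrist"],
        "frames": [{"people": [{"pose_keypoints_2d": small}, {"pose_keypoints_2d": big}]}],
    }
    path = tmp_path / "two.json"
    path.write_text(json.dumps(doc))
    seq = read_pose_json(path)
    assert seq.frames[0].keypoints["left_wrist"].x == 10.0


@pytest.mark.parametrize(
    "content,exc",
    [
        ("{not json", FormatError),
        ("", FormatError),
        (json.dumps({"frames": []}), FormatError),  # header fields missing
    ],
)
def test_malformed_files_raise_format_errors(tmp_path, content, exc):
    path = tmp_path / "bad.json"
    path.write_text(content)
    with pytest.raises(exc):
        read_pose_json(path)


def test_inconsistent_joint_count_raises_schema_error(tmp_path):
    doc = {
        "child_id": "x",
        "frame_rate": 30.0,
        "image_width": 10,
        "image_height": 10,
        "joint_names": ["left_wrist", "right_wrist"],
        "frames": [
            {"people": [{"pose_keypoints_2d": [1, 1, 0.9, 2, 2, 0.9]}]},
            {"people": [{"pose_keypoints_2d": [1, 1, 0.9]}]},
        ],
    }
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(SchemaError):
        read_pose_json(path)


class TestLabels:
    def test_valid_rows(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("child_id,label\nc1,B\nc2,D\n")
        table = read_labels(p)
        assert len(table) == 2
        assert table["c1"] is am.AttachmentLabel.B
        assert table["c2"] is am.AttachmentLabel.D

    def test_unknown_code_names_the_row(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("child_id,label\nc1,B\nc3,X\n")
        with pytest.raises(LabelError, match="line 3"):
            read_labels(p)

    def test_duplicate_child_id(self, tmp_path):
        p = tmp_path / "l.csv"
        p.write_text("child_id,label\nc1,B\nc1,A\n")
        with pytest.raises(LabelError, match="duplicate"):
            read_labels(p)

    def test_published_marginals_secure_count(self, tmp_path):
        # 61 rows with the published MCAST column totals: 43 B, 4 A, 10 C, 4 D
        rows = ["child_id,label"]
        i = 0
        for code, count in (("B", 43), ("A", 4), ("C", 10), ("D", 4)):
            for _ in range(count):
                rows.append(f"k{i},{code}")
                i += 1
        p = tmp_path / "marg.csv"
        p.write_text("\n".join(rows) + "\n")
        table = read_labels(p)
        assert len(table) == 61
        assert sum(1 for v in table.values() if v.secure) == 43
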