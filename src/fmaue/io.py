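"""Readers and writers for recordings, force frames and assessment reports.

Recordings travel as versioned JSON (``schema_version`` 1): positions in
metres, times in seconds, forces in newtons.  Force frames may additionally
be read/written as CSV with one frame per row — either bare 256-column
row-major grids, or rows prefixed with ``motion_id, side, t`` metadata.

Left-affected subjects are mirrored at load time (z -> -z across the
sagittal plane, left/right joint names swapped) so that all downstream
kinematics is written once for a right-affected canonical orientation.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .datamodel import (
    GRID_SHAPE,
    AssessmentReport,
    DimensionError,
    ForceFrame,
    HandTrack,
    MotionClip,
    Recording,
    SchemaError,
    ValidationError,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_force_frames",
    "write_force_frames",
    "write_report",
    "read_report",
    "mirror_recording",
]

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return obj[key]


# ---------------------------------------------------------------------------
# recordings


def _clip_to_json(clip: MotionClip) -> dict:
    d = {
        "motion_id": clip.motion_id,
        "side": clip.side,
        "fs": clip.fs,
        "body": {
            "t": clip.t.tolist(),
            "joints": {k: v.tolist() for k, v in sorted(clip.joints.items())},
        },
    }
    if clip.hand is not None:
        d["hand"] = {"t": clip.hand.t.tolist(), "landmarks": clip.hand.landmarks.tolist()}
    return d


def _clip_from_json(d: dict, where: str) -> MotionClip:
    body = _require(d, "body", where)
    hand = None
    if d.get("hand") is not None:
        h = d["hand"]
        try:
            hand = HandTrack(
                t=np.asarray(_require(h, "t", f"{where}.hand"), float),
                landmarks=np.asarray(_require(h, "landmarks", f"{where}.hand"), float),
            )
        except ValidationError as exc:
            raise SchemaError(f"{where}.hand: {exc}") from exc
    try:
        return MotionClip(
            motion_id=_require(d, "motion_id", where),
            side=_require(d, "side", where),
            fs=float(_require(d, "fs", where)),
            t=np.asarray(_require(body, "t", f"{where}.body"), float),
            joints={
                k: np.asarray(v, float)
                for k, v in _require(body, "joints", f"{where}.body").items()
            },
            hand=hand,
        )
    except ValidationError as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def write_recording(recording: Recording, path: PathLike) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": recording.subject_id,
        "affected_side": recording.affected_side,
        "mirrored": recording.mirrored,
        "clips": [_clip_to_json(c) for c in recording.clips],
        "force_frames": [
            {
                "motion_id": f.motion_id,
                "side": f.side,
                "t": f.t,
                "grid": f.grid.tolist(),
            }
            for f in recording.force_frames
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True), encoding="utf-8")


def read_recording(path: PathLike, mirror_left: bool = True) -> Recording:
    """Read a recording JSON file; validates pairing and all invariants.

    With ``mirror_left`` (default), every clip recorded on the left arm
    (identified by carrying ``*_L`` arm joints without their ``*_R``
    counterparts) is reflected across the sagittal plane to the canonical
    right-arm orientation at load time, so downstream kinematics is written
    once.  Force-grid features are mirror-invariant and are left untouched.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema_version {version!r}")
    clips = []
    for i, cd in enumerate(doc.get("clips", [])):
        where = f"clips[{i}]" + (f" ({cd.get('motion_id')}/{cd.get('side')})" if isinstance(cd, dict) else "")
        clips.append(_clip_from_json(cd, where))
    frames = []
    for i, fd in enumerate(doc.get("force_frames", [])):
        where = f"force_frames[{i}]"
        try:
            frames.append(
                ForceFrame(
                    t=float(_require(fd, "t", where)),
                    grid=np.asarray(_require(fd, "grid", where), float),
                    motion_id=_require(fd, "motion_id", where),
                    side=_require(fd, "side", where),
                )
            )
        except ValidationError as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    rec = Recording(
        subject_id=str(_require(doc, "subject_id", "recording")),
        affected_side=_require(doc, "affected_side", "recording"),
        clips=clips,
        force_frames=frames,
        mirrored=bool(doc.get("mirrored", False)),
    )
    rec.check_paired()
    if mirror_left:
        rec.clips = [_canonicalise_clip(c) for c in rec.clips]
    return rec


def _mirror_clip(c: MotionClip) -> MotionClip:
    joints = {_swap_lr(k): v * np.array([1.0, 1.0, -1.0]) for k, v in c.joints.items()}
    hand = None
    if c.hand is not None:
        hand = HandTrack(
            t=c.hand.t.copy(), landmarks=c.hand.landmarks * np.array([1.0, 1.0, -1.0])
        )
    return MotionClip(
        motion_id=c.motion_id, side=c.side, fs=c.fs, t=c.t.copy(), joints=joints, hand=hand
    )


def _canonicalise_clip(c: MotionClip) -> MotionClip:
    left_arm = any(j in c.joints for j in ("ELBOW_L", "WRIST_L"))
    right_arm = any(j in c.joints for j in ("ELBOW_R", "WRIST_R"))
    if left_arm and not right_arm:
        return _mirror_clip(c)
    return c


def _swap_lr(name: str) -> str:
    if name.endswith("_L"):
        return name[:-2] + "_R"
    if name.endswith("_R"):
        return name[:-2] + "_L"
    return name


def mirror_recording(recording: Recording) -> Recording:
    """Reflect across the sagittal plane (z -> -z) and swap L/R joint names.

    Used for left-affected subjects so the affected arm always appears as the
    canonical right arm.  Hand landmarks are reflected the same way; angles
    are reflection-invariant because they are built from dot/cross magnitudes
    with side-consistent sign conventions.
    """
    clips = []
    for c in recording.clips:
        joints = {_swap_lr(k): v * np.array([1.0, 1.0, -1.0]) for k, v in c.joints.items()}
        hand = None
        if c.hand is not None:
            hand = HandTrack(t=c.hand.t.copy(), landmarks=c.hand.landmarks * np.array([1.0, 1.0, -1.0]))
        clips.append(
            MotionClip(
                motion_id=c.motion_id,
                side=c.side,
                fs=c.fs,
                t=c.t.copy(),
                joints=joints,
                hand=hand,
            )
        )
    frames = [
        ForceFrame(t=f.t, grid=f.grid[:, ::-1].copy(), motion_id=f.motion_id, side=f.side)
        for f in recording.force_frames
    ]
    return Recording(
        subject_id=recording.subject_id,
        affected_side=recording.affected_side,
        clips=clips,
        force_frames=frames,
        mirrored=True,
    )


# ---------------------------------------------------------------------------
# force frames as CSV


def write_force_frames(frames: Sequence[ForceFrame], path: PathLike) -> None:
    """One frame per row: motion_id, side, t, then 256 row-major cell forces."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["motion_id", "side", "t"] + [f"c{i:03d}" for i in range(256)])
        for f in frames:
            writer.writerow(
                [f.motion_id, f.side, repr(float(f.t))]
                + [repr(float(x)) for x in f.grid.ravel()]
            )


def read_force_frames(
    path: PathLike,
    motion_id: Optional[str] = None,
    side: Optional[str] = None,
    fs: float = 30.0,
) -> list[ForceFrame]:
    """Read force frames from CSV (or a JSON list of frame objects).

    Two CSV dialects are accepted: rows of exactly 256 values (row-major
    16x16 grid; ``motion_id``/``side`` must then be given, times are assigned
    at 1/``fs`` spacing), or rows of ``motion_id, side, t`` + 256 values as
    written by :func:`write_force_frames`.
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        doc = json.loads(p.read_text(encoding="utf-8"))
        return [
            ForceFrame(
                t=float(_require(fd, "t", f"frames[{i}]")),
                grid=np.asarray(_require(fd, "grid", f"frames[{i}]"), float),
                motion_id=fd.get("motion_id", motion_id),
                side=fd.get("side", side),
            )
            for i, fd in enumerate(doc)
        ]
    frames: list[ForceFrame] = []
    k = 0
    with open(p, newline="", encoding="utf-8") as fh:
        for row_idx, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            if row_idx == 0 and row[0].strip().lower() in ("motion_id", "c000"):
                continue  # header
            if len(row) == 256:
                if motion_id is None or side is None:
                    raise SchemaError(
                        "bare 256-column force CSV needs motion_id and side arguments"
                    )
                mid, sd, t = motion_id, side, k / fs
                values = row
            elif len(row) == 259:
                mid, sd, t = row[0].strip(), row[1].strip(), float(row[2])
                values = row[3:]
            else:
                raise DimensionError(
                    f"row {row_idx}: expected 256 force values (got {len(row)} columns)"
                )
            grid = np.asarray([float(x) for x in values], float).reshape(GRID_SHAPE)
            frames.append(ForceFrame(t=float(t), grid=grid, motion_id=mid, side=sd))
            k += 1
    return frames


# ---------------------------------------------------------------------------
# reports


def write_report(report: AssessmentReport, path: PathLike) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": report.subject_id,
        "item_scores": {str(k): v for k, v in sorted(report.item_scores.items())},
        "sub_scores": {str(k): v for k, v in sorted(report.sub_scores.items())},
        "total": report.total,
        "severity": report.severity,
        "features": {
            str(k): [{n: float(x) for n, x in sub.items()} for sub in subs]
            for k, subs in sorted(report.features.items())
        },
        "diagnostics": list(report.diagnostics),
    }
    try:
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: PathLike) -> AssessmentReport:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return AssessmentReport(
        subject_id=_require(doc, "subject_id", "report"),
        item_scores={int(k): int(v) for k, v in _require(doc, "item_scores", "report").items()},
        sub_scores={int(k): [int(x) for x in v] for k, v in doc.get("sub_scores", {}).items()},
        total=int(_require(doc, "total", "report")),
        severity=_require(doc, "severity", "report"),
        features={
            int(k): [dict(sub) for sub in v] for k, v in doc.get("features", {}).items()
        },
        diagnostics=list(doc.get("diagnostics", [])),
    )
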