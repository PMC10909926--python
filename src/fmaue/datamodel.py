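"""Domain types for automated upper-limb motor-function assessment.

The assessment compares the hemiplegic (affected) upper limb against the
contralateral healthy limb.  A recording session therefore contains, for each
test motion, a pair of clips — one per side — holding time-stamped 3-D body
joint positions (Azure-Kinect-style skeleton vocabulary, metres) and, where a
motion needs hand posture, 21 hand landmarks per frame (MediaPipe hand node
numbering, index 0 = wrist).  Grasp motions additionally carry sequences of
16x16 grids of contact forces in newtons from a distributed thin-film
pressure sensor (150 mm x 150 mm, 7.5 mm cell pitch).

All containers are plain dataclasses over numpy arrays; validation is
explicit and happens at construction / parse time so that non-finite
coordinates or malformed grids never propagate silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BODY_JOINTS",
    "MOTION_IDS",
    "FORCE_MOTIONS",
    "SIDES",
    "GRID_SHAPE",
    "GRID_SIZE_MM",
    "CELL_PITCH_MM",
    "N_HAND_LANDMARKS",
    "ValidationError",
    "SchemaError",
    "UnpairedSideError",
    "DimensionError",
    "GeometryError",
    "JointSample",
    "HandSample",
    "HandTrack",
    "MotionClip",
    "ForceFrame",
    "Recording",
    "AssessmentReport",
]

#: Canonical body-joint vocabulary (Azure Kinect naming, subset used here).
BODY_JOINTS = (
    "PELVIS",
    "SPINE_CHEST",
    "NECK",
    "SHOULDER_L",
    "SHOULDER_R",
    "ELBOW_L",
    "ELBOW_R",
    "WRIST_L",
    "WRIST_R",
    "HIP_L",
    "HIP_R",
    "NOSE",
    "HANDTIP_L",
    "HANDTIP_R",
)

MOTION_IDS = tuple(f"M{i}" for i in range(1, 22))
#: Grasp motions measured with the pressure grid: hook, lateral pinch,
#: pincer, cylinder and sphere grasp.
FORCE_MOTIONS = ("M16", "M17", "M18", "M19", "M20")
SIDES = ("affected", "healthy")

GRID_SHAPE = (16, 16)
#: 256 sensing units of 7.5 mm x 7.5 mm distributed in a 150 mm x 150 mm
#: square; the 9.375 mm centre-to-centre pitch leaves gaps between cells.
GRID_SIZE_MM = 150.0
CELL_SIZE_MM = 7.5
CELL_PITCH_MM = GRID_SIZE_MM / GRID_SHAPE[0]

N_HAND_LANDMARKS = 21
#: Hand landmark indices (MediaPipe numbering).
LM_WRIST = 0
LM_THUMB = (1, 2, 3, 4)
LM_INDEX = (5, 6, 7, 8)
LM_MIDDLE = (9, 10, 11, 12)
LM_RING = (13, 14, 15, 16)
LM_LITTLE = (17, 18, 19, 20)


class ValidationError(ValueError):
    """A value violates a domain invariant (negative force, NaN position...)."""


class SchemaError(ValidationError):
    """A file does not conform to the documented schema."""


class UnpairedSideError(SchemaError):
    """A motion is present for one side only; assessment needs both."""


class DimensionError(SchemaError):
    """Array shape / cell count mismatch."""


class GeometryError(ValueError):
    """Degenerate geometry (zero-length segment, coincident landmarks)."""


def _as_finite(a, name: str, shape=None) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if shape is not None and arr.shape != shape:
        raise DimensionError(f"{name}: expected shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite value")
    return arr


@dataclass
class JointSample:
    """One time-stamped frame of named 3-D joint positions (metres)."""

    t: float
    joints: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"JointSample.t must be >= 0, got {self.t}")
        self.joints = {
            str(k): _as_finite(v, f"joint {k}", shape=(3,)) for k, v in self.joints.items()
        }

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.joints]
        if missing:
            raise ValidationError(f"missing joints: {missing}")


@dataclass
class HandSample:
    """One frame of 21 hand landmarks; index 0 is the wrist origin."""

    t: float
    landmarks: np.ndarray

    def __post_init__(self) -> None:
        self.landmarks = _as_finite(
            self.landmarks, "hand landmarks", shape=(N_HAND_LANDMARKS, 3)
        )
        if self.t < 0:
            raise ValidationError(f"HandSample.t must be >= 0, got {self.t}")


@dataclass
class HandTrack:
    """A sequence of hand-landmark frames stored columnar: (n,) times, (n, 21, 3)."""

    t: np.ndarray
    landmarks: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_finite(self.t, "hand t")
        n = self.t.shape[0]
        self.landmarks = _as_finite(
            self.landmarks, "hand landmarks", shape=(n, N_HAND_LANDMARKS, 3)
        )
        _check_times(self.t, "hand")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def sample(self, i: int) -> HandSample:
        return HandSample(t=float(self.t[i]), landmarks=self.landmarks[i])


def _check_times(t: np.ndarray, what: str) -> None:
    if t.ndim != 1 or t.shape[0] == 0:
        raise ValidationError(f"{what}: empty or non-1D time axis")
    if t[0] < 0:
        raise ValidationError(f"{what}: negative time stamp")
    if t.shape[0] > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError(f"{what}: time stamps must be strictly increasing")


@dataclass
class MotionClip:
    """Joint trajectories of one test motion, one side.

    ``joints`` maps joint name -> (n, 3) positions; ``t`` is the shared (n,)
    time axis.  ``hand`` is present only for motions that need finger / palm
    posture.  ``fs`` must exceed 24 Hz so the 12 Hz low-pass conditioning
    stage is below Nyquist.
    """

    motion_id: str
    side: str
    fs: float
    t: np.ndarray
    joints: dict[str, np.ndarray]
    hand: Optional[HandTrack] = None

    def __post_init__(self) -> None:
        if self.motion_id not in MOTION_IDS:
            raise ValidationError(f"unknown motion_id {self.motion_id!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if not self.fs > 24.0:
            raise ValidationError(
                f"fs must exceed 24 Hz (low-pass cutoff 12 Hz), got {self.fs}"
            )
        self.t = _as_finite(self.t, f"{self.motion_id} t")
        _check_times(self.t, self.motion_id)
        n = self.t.shape[0]
        self.joints = {
            str(k): _as_finite(v, f"{self.motion_id} joint {k}", shape=(n, 3))
            for k, v in self.joints.items()
        }
        if not self.joints:
            raise ValidationError(f"{self.motion_id}: body trajectory is empty")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self)

    def sample(self, i: int) -> JointSample:
        return JointSample(t=float(self.t[i]), joints={k: v[i] for k, v in self.joints.items()})

    def require_joints(self, *names: str) -> None:
        missing = [n for n in names if n not in self.joints]
        if missing:
            raise ValidationError(f"{self.motion_id}/{self.side}: missing joints {missing}")


@dataclass
class ForceFrame:
    """One 16x16 grid of contact forces (newtons) from the pressure sensor."""

    t: float
    grid: np.ndarray
    motion_id: str
    side: str

    def __post_init__(self) -> None:
        if self.motion_id not in FORCE_MOTIONS:
            raise ValidationError(
                f"force frames only exist for {FORCE_MOTIONS}, got {self.motion_id!r}"
            )
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        self.grid = _as_finite(self.grid, "force grid", shape=GRID_SHAPE)
        if np.any(self.grid < 0):
            raise ValidationError("force grid contains negative forces")
        if self.t < 0:
            raise ValidationError("force frame time stamp is negative")


@dataclass
class Recording:
    """A full assessment session: paired clips and force frames for a subject."""

    subject_id: str
    affected_side: str  # "left" | "right" (anatomical side of hemiplegia)
    clips: list[MotionClip] = field(default_factory=list)
    force_frames: list[ForceFrame] = field(default_factory=list)
    mirrored: bool = False  # True once left-affected data was mirrored to canonical

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValidationError(
                f"affected_side must be 'left' or 'right', got {self.affected_side!r}"
            )

    def clip(self, motion_id: str, side: str) -> MotionClip:
        for c in self.clips:
            if c.motion_id == motion_id and c.side == side:
                return c
        raise KeyError(f"no clip for {motion_id}/{side}")

    def has_clip(self, motion_id: str, side: str) -> bool:
        return any(c.motion_id == motion_id and c.side == side for c in self.clips)

    def frames(self, motion_id: str, side: str) -> list[ForceFrame]:
        return [f for f in self.force_frames if f.motion_id == motion_id and f.side == side]

    def check_paired(self) -> None:
        """Every motion present for one side must be present for the other."""
        seen: dict[tuple[str, str], set[str]] = {}
        for c in self.clips:
            seen.setdefault(("clip", c.motion_id), set()).add(c.side)
        for f in self.force_frames:
            seen.setdefault(("force", f.motion_id), set()).add(f.side)
        for (kind, mid), sides in sorted(seen.items()):
            if sides != set(SIDES):
                missing = set(SIDES) - sides
                raise UnpairedSideError(
                    f"{kind} {mid}: missing {sorted(missing)} side recording"
                )


@dataclass
class AssessmentReport:
    """Scored assessment: 30 item scores in {0,1,2}, total, severity class.

    ``features`` keeps the per-item, per-sub-motion fuzzy inputs for clinical
    audit; ``diagnostics`` lists items that could not be scored (they are
    excluded from the total, never silently zeroed).
    """

    subject_id: str
    item_scores: dict[int, int]
    total: int
    severity: str
    features: dict[int, list[dict[str, float]]] = field(default_factory=dict)
    sub_scores: dict[int, list[int]] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for item, s in self.item_scores.items():
            if s not in (0, 1, 2):
                raise ValidationError(f"item {item}: score {s} outside {{0,1,2}}")
        if self.total != sum(self.item_scores.values()):
            raise ValidationError("total must equal the sum of item scores")
        if self.severity not in ("severe", "moderate", "mild"):
            raise ValidationError(f"unknown severity {self.severity!r}")
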