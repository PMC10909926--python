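"""Joint coordinate systems and joint-angle traces.

Angles follow the ISB recommendation of expressing segment motion in a
thorax-fixed frame: Y up the trunk (spine-chest to neck), X anterior,
Z right-lateral.  All traces are functions of relative geometry only, so a
rigid rotation + translation of every joint leaves every angle unchanged.

Conventions (canonical right arm; left-arm data is mirrored at load time):

* shoulder elevation / retraction — inclination of the neck->shoulder vector
  above the horizontal plane / behind the frontal plane (signed, degrees);
* shoulder abduction / flexion — humerus elevation projected onto the
  frontal / sagittal plane of the thorax (via elevation angle and plane of
  elevation of the humerus axis);
* shoulder axial rotation — rotation of the forearm about the humerus axis
  relative to the thorax anterior direction (requires a flexed elbow);
* elbow flexion — 180 deg minus the interior upper-arm/forearm angle, so a
  fully extended arm reads 0 deg;
* forearm pronation/supination — rotation of the palm normal about the
  forearm axis, relative to the posture at the start of the clip;
* wrist flexion/extension — signed angle between the forearm axis and the
  hand axis (wrist -> middle-finger base), dorsiflexion positive;
* finger bend — arccos angle between the per-finger proximal and distal
  landmark vectors (thumb: 3->4 vs 0->2; index: 0->6 vs 7->8; middle:
  0->9 vs 10->12; ring: 0->13 vs 14->16; little: 0->17 vs 18->20).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .datamodel import GeometryError, JointSample, MotionClip, ValidationError
from .preprocess import resample_to

__all__ = [
    "FrameTriad",
    "AngleTrace",
    "ANGLE_LABELS",
    "thorax_frame",
    "shoulder_frame",
    "shoulder_angles",
    "elbow_flexion",
    "shoulder_elevation_retraction",
    "finger_bend_angle",
    "angle_traces",
]

_EPS = 1e-9


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise GeometryError(f"degenerate {what} (zero length)")
    return v / n


def _unit_rows(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        raise GeometryError(f"degenerate {what} (zero length) at some sample")
    return v / n


@dataclass(frozen=True)
class FrameTriad:
    """Right-handed orthonormal segment frame (columns X, Y, Z)."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name, v in (("X", self.x), ("Y", self.y), ("Z", self.z)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise GeometryError(f"{name} axis is not unit length")
        for a, b, nm in ((self.x, self.y, "X.Y"), (self.y, self.z, "Y.Z"), (self.z, self.x, "Z.X")):
            if abs(float(np.dot(a, b))) > 1e-9:
                raise GeometryError(f"axes not orthogonal ({nm})")
        if np.linalg.det(self.rotation) < 0:
            raise GeometryError("left-handed frame")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns X, Y, Z (frame axes in parent coordinates)."""
        return np.stack([self.x, self.y, self.z], axis=1)


@dataclass
class AngleTrace:
    """A named joint-angle time series in degrees."""

    name: str
    t: np.ndarray
    value: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.value = np.asarray(self.value, float)
        if self.t.shape != self.value.shape:
            raise ValidationError("AngleTrace t/value length mismatch")
        if not np.all(np.isfinite(self.value)):
            raise ValidationError(f"AngleTrace {self.name}: non-finite angle")

    def __len__(self) -> int:
        return int(self.t.shape[0])


# ---------------------------------------------------------------------------
# segment frames


def _thorax_axes_from(spine_chest, neck, shoulder_l, shoulder_r):
    y = _unit_rows(neck - spine_chest, "spine-chest -> neck")
    sl = shoulder_r - shoulder_l
    x = np.cross(y, sl)
    x = _unit_rows(x, "thorax anterior axis")
    z = np.cross(x, y)
    return x, y, z


def thorax_frame(sample: JointSample) -> FrameTriad:
    """Thorax frame: Y spine-chest->neck, X anterior, Z right-lateral.

    The anterior axis is the normal of the plane spanned by the trunk axis
    and the inter-shoulder line, oriented ventrally.
    """
    sample.require("SPINE_CHEST", "NECK", "SHOULDER_L", "SHOULDER_R")
    x, y, z = _thorax_axes_from(
        sample.joints["SPINE_CHEST"][None],
        sample.joints["NECK"][None],
        sample.joints["SHOULDER_L"][None],
        sample.joints["SHOULDER_R"][None],
    )
    return FrameTriad(origin=sample.joints["SPINE_CHEST"], x=x[0], y=y[0], z=z[0])


def shoulder_frame(sample: JointSample, side: str = "right") -> FrameTriad:
    """Humerus frame: Y elbow->shoulder; X from the forearm component
    perpendicular to the humerus (falls back to a deterministic perpendicular
    when the arm is straight, where axial orientation is unobservable)."""
    sfx = "_R" if side == "right" else "_L"
    sample.require("SHOULDER" + sfx, "ELBOW" + sfx)
    sh = sample.joints["SHOULDER" + sfx]
    el = sample.joints["ELBOW" + sfx]
    y = _unit(sh - el, "humerus axis")
    f = None
    if "WRIST" + sfx in sample.joints:
        fa = sample.joints["WRIST" + sfx] - el
        perp = fa - np.dot(fa, y) * y
        if np.linalg.norm(perp) > 1e-6:
            f = perp / np.linalg.norm(perp)
    if f is None:
        # straight arm: pick the axis least aligned with y, project out y
        e = np.zeros(3)
        e[int(np.argmin(np.abs(y)))] = 1.0
        perp = e - np.dot(e, y) * y
        f = perp / np.linalg.norm(perp)
    x = f
    z = np.cross(x, y)
    z /= np.linalg.norm(z)
    x = np.cross(y, z)
    return FrameTriad(origin=sh, x=x, y=y, z=z)


def shoulder_angles(thorax: FrameTriad, shoulder: FrameTriad) -> tuple[float, float, float]:
    """Y-X-Y Euler decomposition of the thorax->humerus rotation.

    Returns ``(plane_of_elevation, elevation, axial_rotation)`` in degrees:
    plane 0 = frontal-plane elevation (abduction), plane 90 = sagittal
    (flexion); elevation in [0, 180]; axial rotation about the humerus axis.
    Near the gimbal singularity (elevation ~ 0 or 180) the full Y rotation is
    assigned to the first angle, deterministically.
    """
    r = thorax.rotation.T @ shoulder.rotation
    y_s = r[:, 1]
    elevation = float(np.degrees(np.arccos(np.clip(y_s[1], -1.0, 1.0))))
    sin_e = np.sqrt(max(0.0, 1.0 - y_s[1] ** 2))
    if sin_e < 1e-6:
        # gimbal: only the sum/difference of the two Y rotations is defined
        plane = float(np.degrees(np.arctan2(r[0, 2], r[0, 0])))
        if y_s[1] < 0:  # elevation ~ 180
            plane = float(np.degrees(np.arctan2(r[0, 2], -r[0, 0])))
        return plane, elevation, 0.0
    plane = float(np.degrees(np.arctan2(-y_s[0], -y_s[2])))
    a = np.radians(plane)
    b = -np.radians(elevation)
    ry_a = np.array(
        [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
    )
    rx_b = np.array(
        [[1, 0, 0], [0, np.cos(b), -np.sin(b)], [0, np.sin(b), np.cos(b)]]
    )
    rem = rx_b.T @ ry_a.T @ r
    axial = float(np.degrees(np.arctan2(rem[0, 2], rem[0, 0])))
    return plane, elevation, axial


# ---------------------------------------------------------------------------
# scalar angle helpers


def elbow_flexion(sample: JointSample, side: str = "right") -> float:
    """Flexion in degrees with 0 = fully extended (collinear arm)."""
    sfx = "_R" if side == "right" else "_L"
    sample.require("SHOULDER" + sfx, "ELBOW" + sfx, "WRIST" + sfx)
    ua = _unit(sample.joints["SHOULDER" + sfx] - sample.joints["ELBOW" + sfx], "upper arm")
    fa = _unit(sample.joints["WRIST" + sfx] - sample.joints["ELBOW" + sfx], "forearm")
    interior = np.degrees(np.arccos(np.clip(np.dot(ua, fa), -1.0, 1.0)))
    return float(180.0 - interior)


def shoulder_elevation_retraction(sample: JointSample, side: str = "right") -> tuple[float, float]:
    """Signed (elevation, retraction) of the neck->shoulder vector, degrees.

    Elevation is the inclination above the horizontal plane (normal: trunk
    Y); retraction the inclination behind the frontal plane.  The anterior
    normal of the frontal plane is built from the hip line when hips are
    tracked — the inter-shoulder line moves with the retracting shoulder and
    would absorb about half the angle — falling back to the thorax frame's
    shoulder-line construction otherwise.
    """
    sfx = "_R" if side == "right" else "_L"
    sample.require("NECK", "SHOULDER" + sfx, "SPINE_CHEST", "SHOULDER_L", "SHOULDER_R")
    tf = thorax_frame(sample)
    if "HIP_L" in sample.joints and "HIP_R" in sample.joints:
        hip_line = sample.joints["HIP_R"] - sample.joints["HIP_L"]
        anterior = _unit(np.cross(tf.y, hip_line), "anterior (hip-line) axis")
    else:
        anterior = tf.x
    sn = sample.joints["SHOULDER" + sfx] - sample.joints["NECK"]
    sn = _unit(sn, "shoulder-neck vector")
    elevation = float(np.degrees(np.arcsin(np.clip(np.dot(sn, tf.y), -1.0, 1.0))))
    retraction = float(np.degrees(np.arcsin(np.clip(-np.dot(sn, anterior), -1.0, 1.0))))
    return elevation, retraction


_FINGER_VECTORS = {
    "thumb": ((3, 4), (0, 2)),
    "index": ((0, 6), (7, 8)),
    "middle": ((0, 9), (10, 12)),
    "ring": ((0, 13), (14, 16)),
    "little": ((0, 17), (18, 20)),
}


def finger_bend_angle(landmarks: np.ndarray, finger: str) -> float | np.ndarray:
    """Bend angle (degrees) of one finger from 21 hand landmarks.

    Accepts a single (21, 3) frame or an (n, 21, 3) track.  The angle is the
    3-D arccos between the finger's proximal reference vector and distal
    segment vector; restricted to a plane it reduces to the classic 2-D
    two-vector pinch-angle formula.
    """
    lm = np.asarray(landmarks, float)
    single = lm.ndim == 2
    if single:
        lm = lm[None]
    try:
        (i1, i2), (j1, j2) = _FINGER_VECTORS[finger]
    except KeyError:
        raise ValidationError(f"unknown finger {finger!r}") from None
    v1 = _unit_rows(lm[:, i2] - lm[:, i1], f"{finger} vector {i1}->{i2}")
    v2 = _unit_rows(lm[:, j2] - lm[:, j1], f"{finger} vector {j1}->{j2}")
    ang = np.degrees(np.arccos(np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)))
    return float(ang[0]) if single else ang


# ---------------------------------------------------------------------------
# vectorized traces over a clip


def _joints(clip: MotionClip, *names: str) -> list[np.ndarray]:
    clip.require_joints(*names)
    return [clip.joints[n] for n in names]


def _thorax_axes(clip: MotionClip):
    sc, nk, sl, sr = _joints(clip, "SPINE_CHEST", "NECK", "SHOULDER_L", "SHOULDER_R")
    return _thorax_axes_from(sc, nk, sl, sr)


def _hand_landmarks_on_body_timebase(clip: MotionClip) -> np.ndarray:
    if clip.hand is None:
        raise ValidationError(f"{clip.motion_id}/{clip.side}: hand landmarks unavailable")
    lm = clip.hand.landmarks
    if len(clip.hand) == len(clip):
        return lm
    return resample_to(lm, len(clip))


def _signed_angle(ref: np.ndarray, v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed angle (radians) from ref to v about axis, rowwise."""
    cross = np.cross(ref, v)
    return np.arctan2(np.sum(cross * axis, axis=-1), np.sum(ref * v, axis=-1))


def _trace_shoulder_elevation(clip: MotionClip) -> np.ndarray:
    xt, yt, _ = _thorax_axes(clip)
    nk, sh = _joints(clip, "NECK", "SHOULDER_R")
    sn = _unit_rows(sh - nk, "shoulder-neck vector")
    return np.degrees(np.arcsin(np.clip(np.sum(sn * yt, axis=-1), -1.0, 1.0)))


def _anterior_axis(clip: MotionClip):
    """Anterior unit axis per sample; prefers the hip line — the shoulder
    line moves with girdle motion (elevation/retraction) and would leak it
    into any angle referenced against it."""
    xt, yt, _ = _thorax_axes(clip)
    if "HIP_L" in clip.joints and "HIP_R" in clip.joints:
        hip_line = clip.joints["HIP_R"] - clip.joints["HIP_L"]
        return _unit_rows(np.cross(yt, hip_line), "anterior (hip-line) axis")
    return xt


def _trace_shoulder_retraction(clip: MotionClip) -> np.ndarray:
    _, yt, _ = _thorax_axes(clip)
    nk, sh = _joints(clip, "NECK", "SHOULDER_R")
    xt = _anterior_axis(clip)
    sn = _unit_rows(sh - nk, "shoulder-neck vector")
    return np.degrees(np.arcsin(np.clip(-np.sum(sn * xt, axis=-1), -1.0, 1.0)))


def _humerus_in_thorax(clip: MotionClip):
    xt, yt, zt = _thorax_axes(clip)
    sh, el = _joints(clip, "SHOULDER_R", "ELBOW_R")
    u = _unit_rows(el - sh, "humerus")
    ux = np.sum(u * xt, axis=-1)
    uy = np.sum(u * yt, axis=-1)
    uz = np.sum(u * zt, axis=-1)
    return ux, uy, uz


def _elevation_plane(ux, uy, uz):
    # atan2 form: well conditioned near zero elevation, unlike arccos
    elevation = np.degrees(np.arctan2(np.hypot(ux, uz), -uy))
    plane = np.arctan2(ux, uz)
    return elevation, plane


def _trace_shoulder_abduction(clip: MotionClip) -> np.ndarray:
    elevation, plane = _elevation_plane(*_humerus_in_thorax(clip))
    return elevation * np.cos(plane)


def _trace_shoulder_flexion(clip: MotionClip) -> np.ndarray:
    elevation, plane = _elevation_plane(*_humerus_in_thorax(clip))
    return elevation * np.sin(plane)


def _trace_shoulder_rotation(clip: MotionClip) -> np.ndarray:
    """Axial humerus rotation from the forearm direction, thorax-referenced.

    Undefined samples (forearm collinear with humerus) inherit the previous
    defined value; a clip with no defined sample raises.
    """
    xt = _anterior_axis(clip)
    sh, el, wr = _joints(clip, "SHOULDER_R", "ELBOW_R", "WRIST_R")
    u = _unit_rows(el - sh, "humerus")
    f = wr - el
    w = f - np.sum(f * u, axis=-1, keepdims=True) * u
    ref = xt - np.sum(xt * u, axis=-1, keepdims=True) * u
    wn = np.linalg.norm(w, axis=-1)
    rn = np.linalg.norm(ref, axis=-1)
    ok = (wn > 1e-6) & (rn > 1e-6)
    if not np.any(ok):
        raise GeometryError("axial rotation undefined for the whole clip (straight arm)")
    ang = np.full(len(clip), np.nan)
    ang[ok] = np.degrees(
        _signed_angle(ref[ok] / rn[ok, None], w[ok] / wn[ok, None], u[ok])
    )
    ang[ok] = np.degrees(np.unwrap(np.radians(ang[ok])))
    # forward/backward fill undefined samples
    idx = np.where(ok, np.arange(len(ang)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(ok)
    idx[idx < 0] = int(first)
    return ang[idx]


def _trace_elbow_flexion(clip: MotionClip) -> np.ndarray:
    sh, el, wr = _joints(clip, "SHOULDER_R", "ELBOW_R", "WRIST_R")
    ua = _unit_rows(sh - el, "upper arm")
    fa = _unit_rows(wr - el, "forearm")
    interior = np.degrees(np.arccos(np.clip(np.sum(ua * fa, axis=-1), -1.0, 1.0)))
    return 180.0 - interior


def _palm_normal(lm: np.ndarray) -> np.ndarray:
    return _unit_rows(np.cross(lm[:, 5] - lm[:, 0], lm[:, 17] - lm[:, 0]), "palm plane")


def _trace_forearm_rotation(clip: MotionClip) -> np.ndarray:
    el, wr = _joints(clip, "ELBOW_R", "WRIST_R")
    lm = _hand_landmarks_on_body_timebase(clip)
    f = _unit_rows(wr - el, "forearm axis")
    n = _palm_normal(lm)
    p = n - np.sum(n * f, axis=-1, keepdims=True) * f
    p = _unit_rows(p, "palm normal projection")
    n0 = n[0]
    r = n0[None, :] - np.sum(n0 * f, axis=-1, keepdims=True) * f
    r = _unit_rows(r, "transported reference")
    ang = _signed_angle(r, p, f)
    return np.degrees(np.unwrap(ang))


def _trace_wrist_flexion(clip: MotionClip) -> np.ndarray:
    el, wr = _joints(clip, "ELBOW_R", "WRIST_R")
    lm = _hand_landmarks_on_body_timebase(clip)
    f = _unit_rows(wr - el, "forearm axis")
    h = _unit_rows(lm[:, 9] - lm[:, 0], "hand axis")
    n = _palm_normal(lm)
    d = n - np.sum(n * f, axis=-1, keepdims=True) * f
    d = _unit_rows(d, "dorsal reference")
    return np.degrees(np.arctan2(np.sum(h * d, axis=-1), np.sum(h * f, axis=-1)))


def _trace_finger_thumb(clip: MotionClip) -> np.ndarray:
    lm = _hand_landmarks_on_body_timebase(clip)
    return np.asarray(finger_bend_angle(lm, "thumb"))


def _trace_finger_four_mean(clip: MotionClip) -> np.ndarray:
    lm = _hand_landmarks_on_body_timebase(clip)
    return np.mean(
        [finger_bend_angle(lm, f) for f in ("index", "middle", "ring", "little")], axis=0
    )


_TRACE_FUNCS = {
    "shoulder_elevation": _trace_shoulder_elevation,
    "shoulder_retraction": _trace_shoulder_retraction,
    "shoulder_abduction": _trace_shoulder_abduction,
    "shoulder_flexion": _trace_shoulder_flexion,
    "shoulder_rotation": _trace_shoulder_rotation,
    "elbow_flexion": _trace_elbow_flexion,
    "forearm_rotation": _trace_forearm_rotation,
    "wrist_flexion": _trace_wrist_flexion,
    "finger_bend_thumb": _trace_finger_thumb,
    "finger_bend_four_mean": _trace_finger_four_mean,
}

_ALIASES = {
    "shoulder_external_rotation": "shoulder_rotation",
    "shoulder_internal_rotation": "shoulder_rotation",
    "elbow_extension": "elbow_flexion",
    "forearm_pronation": "forearm_rotation",
    "forearm_supination": "forearm_rotation",
    "wrist_dorsiflexion": "wrist_flexion",
}

ANGLE_LABELS = tuple(sorted(set(_TRACE_FUNCS) | set(_ALIASES)))


def angle_traces(clip: MotionClip, needed: Iterable[str]) -> dict[str, AngleTrace]:
    """Compute the requested angle traces for a (pre-filtered) clip.

    Unknown labels raise; labels whose landmark set is unavailable raise a
    :class:`ValidationError` naming the clip, so callers can mark the item
    unscorable rather than silently skipping it.
    """
    out: dict[str, AngleTrace] = {}
    for label in needed:
        key = _ALIASES.get(label, label)
        if key not in _TRACE_FUNCS:
            raise ValidationError(f"unknown angle label {label!r}")
        value = _TRACE_FUNCS[key](clip)
        out[label] = AngleTrace(name=label, t=clip.t.copy(), value=value, fs=clip.fs)
    return out
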