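"""Synthetic paired recordings with controllable, known impairment.

Generates healthy/affected clip pairs for all 21 motions plus force-frame
stacks for the five grasps, so every pipeline stage — and the end-to-end
score — can be tested against generator ground truth without hardware or
patient data.

Healthy motion follows minimum-jerk angle profiles (smooth, zero endpoint
velocity) on a fixed posed skeleton; the affected side re-executes the same
profile with its range scaled by ``rom_scale``, its total excursion per unit
time scaled by ``velocity_scale`` (realised as repeated cycles of the scaled
profile), an optional 5 Hz sinusoidal tremor, and Gaussian position noise.
Composite synergy clips (M1, M2) run their degrees of freedom in sequential
phases so each scored angle has a clean excursion; the generator poses the
hand with the same twist-transport convention the kinematics module
measures, so commanded angles are recovered exactly in the noise-free limit.
These are deliberate stand-ins for patient kinematics, not claims about it:
real hemiparetic movement shows synergy coupling, variable timing and
occlusion artefacts that this generator does not emulate.

Force frames place per-finger Gaussian contact blobs (peak amplitudes in
the ranges observed for a healthy cylinder grasp, thumb ~12 N) plus a palm
patch on the 16x16 grid, with cells below a 0.3 N sensor floor zeroed; the
affected grid is scaled by ``force_scale`` with ``disabled_fingers``' blobs
removed.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .datamodel import ForceFrame, HandTrack, MotionClip, Recording

__all__ = ["ImpairmentProfile", "gen_recording", "gen_force_frames", "gen_clip"]

FS_DEFAULT = 30.0
PHASE_DURATION = 5.0  # seconds per sub-motion / phase
TREMOR_HZ = 5.0

# skeleton constants (metres)
_STATIC = {
    "PELVIS": (0.0, 0.95, 0.0),
    "SPINE_CHEST": (0.0, 1.25, 0.0),
    "NECK": (0.0, 1.45, 0.0),
    "SHOULDER_L": (0.0, 1.40, -0.20),
    "SHOULDER_R": (0.0, 1.40, 0.20),
    "HIP_L": (0.0, 0.92, -0.10),
    "HIP_R": (0.0, 0.92, 0.10),
    "NOSE": (0.05, 1.58, 0.0),
}
L_UA = 0.28  # upper arm
L_FA = 0.25  # forearm
L_HAND = 0.15  # wrist -> hand tip

FINGERS = ("thumb", "index", "middle", "ring", "little")


@dataclass
class ImpairmentProfile:
    """Controllable deficit of the affected side relative to the healthy side.

    ``rom_scale`` / ``velocity_scale`` / ``force_scale`` in [0, 1] scale the
    affected range of motion, mean excursion rate and grip force;
    ``tremor_amplitude`` (degrees) adds a 5 Hz sinusoid to the moving degree
    of freedom; ``noise_sd`` (metres) is Gaussian position jitter on body
    joints (hand landmarks get a fifth of it — close-range landmark jitter
    is smaller).  The 0.1 mm default models the residual jitter left after
    zero-phase smoothing, so recovered features are dominated by the
    commanded deficit; raise it to study noise robustness.  ``per_motion``
    overrides scales for single motions, e.g. ``{"M5": {"rom_scale": 0.3}}``.
    """

    rom_scale: float = 1.0
    velocity_scale: float = 1.0
    tremor_amplitude: float = 0.0
    force_scale: float = 1.0
    disabled_fingers: frozenset = frozenset()
    noise_sd: float = 0.0001
    seed: int = 0
    per_motion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("rom_scale", "velocity_scale", "force_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.disabled_fingers) - set(FINGERS)
        if unknown:
            raise ValueError(f"unknown fingers: {sorted(unknown)}")

    def scales_for(self, motion_id: str) -> tuple[float, float, float]:
        ov = dict(self.per_motion.get(motion_id, {}))
        return (
            float(ov.get("rom_scale", self.rom_scale)),
            float(ov.get("velocity_scale", self.velocity_scale)),
            float(ov.get("force_scale", self.force_scale)),
        )


# ---------------------------------------------------------------------------
# angle profiles


def _minjerk(q: np.ndarray) -> np.ndarray:
    q = np.clip(q, 0.0, 1.0)
    return 10 * q**3 - 15 * q**4 + 6 * q**5


def _wave(u: np.ndarray, k: float = 1.0) -> np.ndarray:
    """There-and-back minimum-jerk wave, k cycles over u in [0, 1]."""
    phase = (u * k) % 1.0
    # the final sample of a whole cycle lands on phase 0 (back at baseline)
    rise = phase <= 0.5
    out = np.empty_like(phase)
    out[rise] = _minjerk(2 * phase[rise])
    out[~rise] = _minjerk(2 - 2 * phase[~rise])
    return out


def _dof(
    n_total: int,
    window: slice,
    base: float,
    amp: float,
    r: float,
    k: float,
    tremor: float,
    t: np.ndarray,
) -> np.ndarray:
    """One degree-of-freedom trace: baseline outside ``window``, a scaled
    wave (+ tremor) inside it."""
    arr = np.full(n_total, base, float)
    n = window.stop - window.start
    u = np.arange(n) / max(n - 1, 1)
    if r > 0 and amp != 0:
        arr[window] = base + amp * r * _wave(u, k)
    if tremor > 0:
        arr[window] += tremor * np.sin(2 * np.pi * TREMOR_HZ * t[window])
    return arr


def _cycles(r: float, v: float) -> float:
    if r <= 0:
        return 1.0
    return max(0.5, v / r)


def _rot(axis: np.ndarray, angle: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Rodrigues rotation, rowwise; axis (n,3) unit, angle (n,), vec (n,3)."""
    a = np.radians(angle)[:, None]
    c, s = np.cos(a), np.sin(a)
    return (
        vec * c
        + np.cross(axis, vec) * s
        + axis * np.sum(axis * vec, axis=-1, keepdims=True) * (1 - c)
    )


# ---------------------------------------------------------------------------
# arm + hand pose construction


def _static_joints(n: int) -> dict[str, np.ndarray]:
    return {k: np.tile(np.asarray(v, float), (n, 1)) for k, v in _STATIC.items()}


def _build_arm(
    n: int,
    elevation: np.ndarray,
    retraction: np.ndarray,
    plane: np.ndarray,
    arm_elev: np.ndarray,
    elbow_flex: np.ndarray,
    axial: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Right-arm chain from angle traces (degrees).

    Returns (shoulder, elbow, wrist, forearm_dir).  ``plane`` is the plane of
    elevation (0 frontal/abduction, 90 sagittal/flexion); ``arm_elev`` the
    humerus elevation; ``axial`` the humerus axial rotation (measured against
    the anterior axis, observable when the elbow is flexed).
    """
    neck = np.tile(np.asarray(_STATIC["NECK"], float), (n, 1))
    sn0 = np.asarray(_STATIC["SHOULDER_R"], float) - np.asarray(_STATIC["NECK"], float)
    l_sn = np.linalg.norm(sn0)
    e = np.radians(elevation)
    rr = np.radians(retraction)
    d = np.stack(
        [-np.sin(rr) * np.cos(e), np.sin(e), np.cos(rr) * np.cos(e)], axis=-1
    )
    shoulder = neck + l_sn * d

    p = np.radians(plane)
    ae = np.radians(arm_elev)
    u = np.stack(
        [np.sin(ae) * np.sin(p), -np.cos(ae), np.sin(ae) * np.cos(p)], axis=-1
    )
    elbow = shoulder + L_UA * u

    # elbow flexion axis perpendicular to the humerus, anchored anteriorly
    x_hat = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    c = np.cross(u, x_hat)
    cn = np.linalg.norm(c, axis=-1, keepdims=True)
    fallback = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    c = np.where(cn > 1e-9, c / np.where(cn > 0, cn, 1.0), fallback)
    v = _rot(c, elbow_flex, u)
    v = _rot(u, axial, v)
    wrist = elbow + L_FA * v
    return shoulder, elbow, wrist, v


def _build_hand(
    wrist: np.ndarray,
    forearm_dir: np.ndarray,
    pronation: np.ndarray,
    wrist_flex: np.ndarray,
    bends: Mapping[str, np.ndarray],
) -> np.ndarray:
    """21 landmarks per frame, posed in the measurement conventions.

    The palm normal is the initial perpendicular reference transported along
    the forearm axis and twisted by ``pronation``; the hand axis is the
    forearm axis tilted by ``wrist_flex`` towards that normal (dorsiflexion
    positive); fingers bend by the commanded angle about an axis
    perpendicular to their proximal reference vector.
    """
    n = wrist.shape[0]
    f = forearm_dir / np.linalg.norm(forearm_dir, axis=-1, keepdims=True)
    f0 = f[0]
    aux = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(f0, aux)) > 0.9:
        aux = np.array([0.0, 1.0, 0.0])
    n0 = np.cross(f0, aux)
    n0 /= np.linalg.norm(n0)
    # transported twist reference
    r = n0[None, :] - np.sum(n0 * f, axis=-1, keepdims=True) * f
    r /= np.linalg.norm(r, axis=-1, keepdims=True)
    normal = _rot(f, pronation, r)
    wf = np.radians(wrist_flex)[:, None]
    h = np.cos(wf) * f + np.sin(wf) * normal
    m = np.cross(normal, h)
    m /= np.linalg.norm(m, axis=-1, keepdims=True)

    lm = np.zeros((n, 21, 3))
    lm[:, 0] = wrist

    def chain(base_idx, seg_idxs, base_off_h, base_off_m, seg_lens, bend):
        base = wrist + base_off_h * h + base_off_m * m
        lm[:, base_idx] = base
        d = base - wrist
        d = d / np.linalg.norm(d, axis=-1, keepdims=True)
        axis = np.cross(d, normal)
        axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
        d_bent = _rot(axis, bend, d)
        pos = base
        # proximal link continues straight; distal links carry the bend
        for idx, ln, dd in zip(seg_idxs, seg_lens, (d, d_bent, d_bent)):
            pos = pos + ln * dd
            lm[:, idx] = pos

    zero = np.zeros(n)
    chain(5, (6, 7, 8), 0.090, -0.030, (0.035, 0.025, 0.022), bends.get("index", zero))
    chain(9, (10, 11, 12), 0.095, -0.010, (0.036, 0.026, 0.023), bends.get("middle", zero))
    chain(13, (14, 15, 16), 0.090, 0.012, (0.033, 0.024, 0.021), bends.get("ring", zero))
    chain(17, (18, 19, 20), 0.082, 0.032, (0.028, 0.020, 0.018), bends.get("little", zero))

    # thumb: landmarks 1-4; reference vector 0->2, bend on segment 3->4
    t_dir = 0.5 * h - 0.866 * m
    t_dir /= np.linalg.norm(t_dir, axis=-1, keepdims=True)
    lm[:, 1] = wrist + 0.025 * t_dir
    lm[:, 2] = wrist + 0.050 * t_dir
    axis_t = np.cross(t_dir, normal)
    axis_t /= np.linalg.norm(axis_t, axis=-1, keepdims=True)
    d_t = _rot(axis_t, bends.get("thumb", zero), t_dir)
    lm[:, 3] = lm[:, 2] + 0.030 * d_t
    lm[:, 4] = lm[:, 3] + 0.025 * d_t
    return lm


# ---------------------------------------------------------------------------
# per-motion recipes

# (phase dof name, baseline, amplitude); composite clips list several phases
_ANGLE_MOTIONS: dict[str, dict] = {
    "M1": {
        "phases": [
            ("elevation", 0.0, 25.0),
            ("retraction", 0.0, 20.0),
            ("abduction", 0.0, 95.0),
            ("axial", 0.0, 35.0),
            ("elbow", 25.0, 60.0),
            ("pronation", 0.0, 50.0),
        ],
        "elbow_base": 25.0,
        "hand": True,
        "integer_cycles": True,
    },
    "M2": {
        "phases": [
            ("axial", 0.0, -35.0),
            ("elbow", 85.0, -60.0),
            ("pronation", 0.0, -50.0),
        ],
        "elbow_base": 85.0,
        "hand": True,
        "integer_cycles": True,
    },
    "M4": {"phases": [("flexion", 0.0, 90.0)], "elbow_base": 0.0, "hand": False},
    "M5": {"phases": [("elbow", 30.0, -30.0)], "elbow_base": 30.0, "hand": False},
    "M6": {"phases": [("pronation", 0.0, 60.0)], "elbow_base": 90.0, "hand": True},
    "M7": {"phases": [("elbow", 30.0, 60.0)], "elbow_base": 30.0, "hand": False},
    "M8": {"phases": [("pronation", 0.0, -60.0)], "elbow_base": 90.0, "hand": True},
    "M9": {"phases": [("abduction", 0.0, 90.0)], "elbow_base": 0.0, "hand": False},
    "M10": {"phases": [("flexion", 90.0, 80.0)], "elbow_base": 0.0, "hand": False},
    "M11": {"phases": [("flexion", 0.0, 35.0)], "elbow_base": 0.0, "hand": False},
    "M12": {"phases": [("wrist", 0.0, 30.0)], "elbow_base": 45.0, "hand": True},
    "M13": {"phases": [("wrist", -30.0, 60.0)], "elbow_base": 45.0, "hand": True},
    "M14": {"phases": [("fingers", 0.0, 80.0)], "elbow_base": 30.0, "hand": True},
    "M15": {"phases": [("fingers", 80.0, -70.0)], "elbow_base": 30.0, "hand": True},
}


def _gen_angle_clip(
    motion_id: str, side: str, profile: ImpairmentProfile, fs: float, rng
) -> MotionClip:
    spec = _ANGLE_MOTIONS[motion_id]
    phases = spec["phases"]
    n_ph = int(round(PHASE_DURATION * fs))
    n = n_ph * len(phases)
    t = np.arange(n) / fs

    if side == "healthy":
        r, v, tremor = 1.0, 1.0, 0.0
    else:
        r, v, _ = profile.scales_for(motion_id)
        tremor = profile.tremor_amplitude
    k = _cycles(r, v)
    if spec.get("integer_cycles"):
        k = max(1.0, round(k))

    dofs = {
        name: np.full(n, 0.0) for name in
        ("elevation", "retraction", "abduction", "flexion", "axial", "pronation", "wrist")
    }
    dofs["elbow"] = np.full(n, float(spec.get("elbow_base", 0.0)))
    finger_bends: dict[str, np.ndarray] = {}
    for i, (dof, base, amp) in enumerate(phases):
        window = slice(i * n_ph, (i + 1) * n_ph)
        if dof == "fingers":
            for fgr in FINGERS:
                finger_bends[fgr] = _dof(n, window, base, amp, r, k, tremor, t)
        else:
            dofs[dof] = _dof(n, window, base, amp, r, k, tremor, t)

    # plane of elevation: abduction phases are frontal, flexion sagittal
    plane = np.where(np.abs(dofs["flexion"]) > 1e-12, 90.0, 0.0)
    arm_elev = dofs["abduction"] + dofs["flexion"]
    shoulder, elbow, wrist, v_dir = _build_arm(
        n, dofs["elevation"], dofs["retraction"], plane, arm_elev, dofs["elbow"], dofs["axial"]
    )
    joints = _static_joints(n)
    joints["SHOULDER_R"] = shoulder
    joints["ELBOW_R"] = elbow
    joints["WRIST_R"] = wrist

    hand = None
    if spec["hand"]:
        lm = _build_hand(wrist, v_dir, dofs["pronation"], dofs["wrist"], finger_bends)
        joints["HANDTIP_R"] = lm[:, 12]
        lm = lm + rng.normal(0.0, profile.noise_sd / 5.0, lm.shape)
        hand = HandTrack(t=t.copy(), landmarks=lm)
    else:
        joints["HANDTIP_R"] = wrist + L_HAND * v_dir

    for name in joints:
        joints[name] = joints[name] + rng.normal(0.0, profile.noise_sd, joints[name].shape)
    return MotionClip(motion_id=motion_id, side=side, fs=fs, t=t, joints=joints, hand=hand)


def _gen_reach_clip(
    motion_id: str, side: str, profile: ImpairmentProfile, fs: float, rng
) -> MotionClip:
    """M3 (hand to lumbar spine) and M21 (finger-nose) task-space clips.

    The moving effector follows a straight minimum-jerk path toward the
    target; the affected side covers ``rom_scale`` of the healthy extent at
    ``velocity_scale`` of the healthy excursion rate.
    """
    n = int(round(PHASE_DURATION * fs))
    t = np.arange(n) / fs
    if side == "healthy":
        r, v, tremor = 1.0, 1.0, 0.0
    else:
        r, v, _ = profile.scales_for(motion_id)
        tremor = profile.tremor_amplitude
    k = _cycles(r, v)
    u = np.arange(n) / max(n - 1, 1)
    w = _wave(u, k) * r

    joints = _static_joints(n)
    if motion_id == "M3":
        start = np.array([0.12, 1.05, 0.30])
        hip_c = 0.5 * (
            np.asarray(_STATIC["HIP_L"], float) + np.asarray(_STATIC["HIP_R"], float)
        )
        # a full healthy reach stops 10% short of the hip centre
        target = start + 0.9 * (hip_c - start)
        path = start[None, :] + w[:, None] * (target - start)[None, :]
        joints["WRIST_R"] = path
        joints["ELBOW_R"] = path + np.array([0.05, 0.20, 0.05])
        joints["HANDTIP_R"] = path + np.array([0.0, -0.05, 0.0])
    else:  # M21
        nose = np.asarray(_STATIC["NOSE"], float)
        start = np.array([nose[0], 0.90, 0.0])  # lap, directly below the nose
        target = np.array([nose[0], nose[1], 0.0])
        path = start[None, :] + w[:, None] * (target - start)[None, :]
        if tremor > 0:
            lateral = np.radians(tremor) * L_FA
            path = path + (lateral * np.sin(2 * np.pi * TREMOR_HZ * t))[:, None] * np.array(
                [0.0, 0.0, 1.0]
            )
        joints["HANDTIP_R"] = path
        joints["WRIST_R"] = path + np.array([0.0, -0.08, 0.0])
        joints["ELBOW_R"] = path + np.array([0.05, -0.30, 0.05])
    for name in joints:
        joints[name] = joints[name] + rng.normal(0.0, profile.noise_sd, joints[name].shape)
    return MotionClip(motion_id=motion_id, side=side, fs=fs, t=t, joints=joints, hand=None)


def gen_clip(
    motion_id: str, side: str, profile: ImpairmentProfile, fs: float = FS_DEFAULT
) -> MotionClip:
    """Generate one clip deterministically (seeded by profile.seed, motion, side)."""
    idx = int(motion_id[1:])
    rng = np.random.default_rng((profile.seed, idx, 0 if side == "affected" else 1))
    if motion_id in _ANGLE_MOTIONS:
        return _gen_angle_clip(motion_id, side, profile, fs, rng)
    if motion_id in ("M3", "M21"):
        return _gen_reach_clip(motion_id, side, profile, fs, rng)
    raise ValueError(f"no clip generator for motion {motion_id!r}")


# ---------------------------------------------------------------------------
# force frames

# blob centres (row, col) on the 16x16 grid and healthy peak amplitudes (N)
_FINGER_BLOBS = {
    "thumb": ((10, 4), 12.2),
    "index": ((4, 6), 7.6),
    "middle": ((3, 8), 6.3),
    "ring": ((4, 10), 4.1),
    "little": ((5, 12), 3.6),
}
_PALM_BLOB = ((11, 8), 2.0, 1.5)  # centre, peak, sigma
_BLOB_SIGMA = 0.6
_SENSOR_FLOOR = 0.3  # N; cells below this are not resolved by the sensor


def _healthy_grid(disabled: frozenset = frozenset()) -> np.ndarray:
    rows, cols = np.mgrid[0:16, 0:16]
    grid = np.zeros((16, 16))
    for name, ((r0, c0), peak) in _FINGER_BLOBS.items():
        if name in disabled:
            continue
        grid += peak * np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * _BLOB_SIGMA**2)))
    (r0, c0), peak, sig = _PALM_BLOB
    grid += peak * np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sig**2)))
    grid[grid < _SENSOR_FLOOR] = 0.0
    return grid


def gen_force_frames(
    profile: ImpairmentProfile,
    motion_id: str,
    n_frames: int = 8,
    fs: float = FS_DEFAULT,
) -> list[ForceFrame]:
    """Force-frame stacks for one grasp motion, both sides.

    The grip ramps up with a minimum-jerk envelope and holds; the healthy
    hand's grid is column-mirrored (it is the other hand).  The affected
    pattern is the healthy one scaled by ``force_scale`` with disabled
    fingers' blobs removed, plus ~1% multiplicative sensor noise (omitted
    when the profile is configured noise-free, ``noise_sd == 0``).
    """
    if motion_id not in ("M16", "M17", "M18", "M19", "M20"):
        raise ValueError(f"{motion_id!r} is not a grasp motion")
    idx = int(motion_id[1:])
    envelope = _minjerk(np.linspace(0.0, 1.2, n_frames))  # reaches 1 and holds
    frames: list[ForceFrame] = []
    for side in ("affected", "healthy"):
        rng = np.random.default_rng((profile.seed, idx, 0 if side == "affected" else 1))
        if side == "healthy":
            base = _healthy_grid()[:, ::-1]
            scale = 1.0
        else:
            _, _, fscale = profile.scales_for(motion_id)
            base = _healthy_grid(frozenset(profile.disabled_fingers))
            scale = fscale
        noise_amp = 0.01 if profile.noise_sd > 0 else 0.0
        for j, env in enumerate(envelope):
            noise = 1.0 + noise_amp * rng.standard_normal(base.shape)
            grid = np.clip(base * scale * env * noise, 0.0, None)
            frames.append(
                ForceFrame(t=j / fs, grid=grid, motion_id=motion_id, side=side)
            )
    return frames


def gen_recording(
    profile: ImpairmentProfile, fs: float = FS_DEFAULT, subject_id: str = "synthetic"
) -> Recording:
    """Full paired recording: clips for M1-M15 and M21, frames for M16-M20."""
    clips = []
    for motion_id in list(_ANGLE_MOTIONS) + ["M3", "M21"]:
        for side in ("affected", "healthy"):
            clips.append(gen_clip(motion_id, side, profile, fs))
    frames: list[ForceFrame] = []
    for motion_id in ("M16", "M17", "M18", "M19", "M20"):
        frames.extend(gen_force_frames(profile, motion_id, fs=fs))
    return Recording(
        subject_id=subject_id,
        affected_side="right",
        clips=clips,
        force_frames=frames,
    )
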