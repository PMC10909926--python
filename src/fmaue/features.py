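"""Per-item feature extraction: motion features and affected/healthy ratios.

Every scored item compares the affected limb against the healthy limb
performing the same motion.  For angle-based items the features are

* ROM   — range of motion, max minus min of the angle trace (degrees);
* MV    — mean absolute angular velocity (degrees/s);
* delta — RMS pointwise deviation between the affected and healthy traces
          after resampling both to a common length n:
          delta = sqrt( sum_i dd_i^2 / n ).

The fuzzy inputs are the dimensionless ratios AROM/HROM and AMV/HMV and the
normalised deviation delta / HROM (healthy ROM is the natural per-subject
scale; the raw delta is in degrees).  Special items use task features:
hand-to-hip length ratio alpha, finger-nose vertical ratio gamma and
shoulder-symmetry ratio beta, fingertip peak speed and mean acceleration,
and thresholded grip-force sums over the 16x16 pressure grid.

All fuzzy inputs are clipped to the [0, 1] ratio domain; the membership
knots extend beyond it (low starts at -0.4, high ends at 1.4) so both domain
edges sit on full low/high plateaus, and an affected side that outperforms
the healthy side saturates at "high" rather than escaping the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import ForceFrame, GeometryError, MotionClip, ValidationError
from .kinematics import AngleTrace, _thorax_axes, _hand_landmarks_on_body_timebase
from .preprocess import resample_to

__all__ = [
    "UNIVERSE_MAX",
    "MotionFeatures",
    "ReachFeatures",
    "ForceFeatures",
    "rom",
    "mean_velocity",
    "deviation_sd",
    "hand_hip_ratio",
    "finger_nose_features",
    "grip_force_total",
    "mirror_force",
    "angle_ratio_features",
]

#: Upper end of every fuzzy input universe (ratio domain [0, 1]; the "high"
#: trapezoid's support extends beyond it so the edge sits on its plateau).
UNIVERSE_MAX = 1.0

#: Default effective-grip threshold (N): the sensor's detection floor.
DEFAULT_FORCE_THRESHOLD = 0.1

#: Default common length for deviation resampling.
DEFAULT_DEVIATION_SAMPLES = 200


def clip_universe(x: float) -> float:
    return float(np.clip(x, 0.0, UNIVERSE_MAX))


@dataclass
class MotionFeatures:
    """ROM / MV of one angle trace (one side)."""

    rom: float
    mv: float


@dataclass
class ReachFeatures:
    """Task features of a reaching clip (hand-to-hip or finger-to-nose)."""

    alpha: float = np.nan  # min hand-hip distance / starting distance
    gamma: float = np.nan  # min vertical fingertip-nose distance / start
    beta: float = np.nan  # L/R shoulder horizontal distance ratio at closest approach
    vmax: float = np.nan  # peak fingertip speed (m/s)
    mean_speed: float = np.nan  # mean fingertip speed (m/s)
    mean_accel: float = np.nan  # mean |fingertip acceleration| (m/s^2)
    move_time: float = np.nan  # onset (speed > 5% vmax) to closest approach (s)


@dataclass
class ForceFeatures:
    """Thresholded grip-force summary of a stack of force frames."""

    total_force: float
    threshold: float
    peak_grid: np.ndarray


# ---------------------------------------------------------------------------
# angle-trace features


def rom(trace: AngleTrace) -> float:
    """Range of motion: max - min of the trace, degrees."""
    if len(trace) == 0:
        raise ValidationError("empty trace")
    return float(np.max(trace.value) - np.min(trace.value))


def mean_velocity(trace: AngleTrace) -> float:
    """Mean absolute angular velocity, degrees/s (first differences x fs)."""
    if len(trace) < 2:
        raise ValidationError("mean velocity needs at least 2 samples")
    return float(np.mean(np.abs(np.diff(trace.value))) * trace.fs)


def deviation_sd(affected: AngleTrace, healthy: AngleTrace, n: int = DEFAULT_DEVIATION_SAMPLES) -> float:
    """RMS pointwise deviation between sides after resampling to length n."""
    if n < 1:
        raise ValidationError(f"deviation sample count must be >= 1, got {n}")
    a = resample_to(affected.value, max(n, 2))[:n] if n >= 2 else affected.value[:1]
    h = resample_to(healthy.value, max(n, 2))[:n] if n >= 2 else healthy.value[:1]
    if a.shape != h.shape:
        raise ValidationError("deviation traces have mismatched lengths after resampling")
    dd = a - h
    return float(np.sqrt(np.sum(dd**2) / dd.shape[0]))


def angle_ratio_features(
    affected: AngleTrace, healthy: AngleTrace, n: int = DEFAULT_DEVIATION_SAMPLES
) -> dict[str, float]:
    """The three fuzzy inputs of an angle item: rom_ratio, mv_ratio, sd_norm."""
    hrom = rom(healthy)
    hmv = mean_velocity(healthy)
    if hrom <= 0 or hmv <= 0:
        raise ValidationError(
            f"uninformative healthy reference for trace {healthy.name!r} "
            f"(HROM={hrom:.3g}, HMV={hmv:.3g})"
        )
    return {
        "rom_ratio": clip_universe(rom(affected) / hrom),
        "mv_ratio": clip_universe(mean_velocity(affected) / hmv),
        "sd_norm": clip_universe(deviation_sd(affected, healthy, n) / hrom),
    }


# ---------------------------------------------------------------------------
# reaching features


def _hip_centre(clip: MotionClip) -> np.ndarray:
    clip.require_joints("HIP_L", "HIP_R")
    return 0.5 * (clip.joints["HIP_L"] + clip.joints["HIP_R"])


def hand_hip_ratio(clip: MotionClip, hand_joint: str = "WRIST_R") -> float:
    """Hand-to-hip motion length ratio alpha = min d(hand, hip centre) / d at start.

    0 means the hand reached the hip centre, 1 means it never moved closer.
    """
    clip.require_joints(hand_joint)
    d = np.linalg.norm(clip.joints[hand_joint] - _hip_centre(clip), axis=-1)
    if d[0] < 1e-9:
        raise GeometryError("hand starts at the hip centre (d_OHC = 0)")
    return float(np.min(d) / d[0])


def _fingertip(clip: MotionClip) -> np.ndarray:
    """Index fingertip (landmark 8) if hand data exists, else the body hand tip."""
    if clip.hand is not None:
        return _hand_landmarks_on_body_timebase(clip)[:, 8]
    clip.require_joints("HANDTIP_R")
    return clip.joints["HANDTIP_R"]


def finger_nose_features(clip: MotionClip) -> ReachFeatures:
    """Finger-nose test features: gamma, beta, vmax, mean |accel|, move time.

    "Vertical" is the thorax Y axis and "horizontal" its orthogonal plane, so
    the features are invariant to camera placement.  gamma = 0 means the
    fingertip reached nose height; gamma = 1 means it never rose at all.
    """
    clip.require_joints("NOSE", "SHOULDER_L", "SHOULDER_R")
    tip = _fingertip(clip)
    nose = clip.joints["NOSE"]
    _, yt, _ = _thorax_axes(clip)
    dd = np.abs(np.sum((nose - tip) * yt, axis=-1))
    if dd[0] < 1e-9:
        raise GeometryError("fingertip starts at nose height (d_FON = 0)")
    i_min = int(np.argmin(dd))
    gamma = float(dd[i_min] / dd[0])

    def _horiz_dist(a: np.ndarray, b: np.ndarray) -> float:
        v = a - b
        v = v - np.sum(v * yt[i_min]) * yt[i_min]
        return float(np.linalg.norm(v))

    d_l = _horiz_dist(tip[i_min], clip.joints["SHOULDER_L"][i_min])
    d_r = _horiz_dist(tip[i_min], clip.joints["SHOULDER_R"][i_min])
    beta = d_l / d_r if d_r > 1e-9 else np.inf

    dt = 1.0 / clip.fs
    vel = np.gradient(tip, dt, axis=0)
    speed = np.linalg.norm(vel, axis=-1)
    vmax = float(np.max(speed))
    acc = np.gradient(vel, dt, axis=0)
    mean_accel = float(np.mean(np.linalg.norm(acc, axis=-1)))
    if vmax > 0:
        onset_idx = int(np.argmax(speed > 0.05 * vmax))
        move_time = max(0.0, float(clip.t[i_min] - clip.t[onset_idx]))
    else:
        move_time = 0.0
    return ReachFeatures(
        gamma=gamma,
        beta=beta,
        vmax=vmax,
        mean_speed=float(np.mean(speed)),
        mean_accel=mean_accel,
        move_time=move_time,
    )


# ---------------------------------------------------------------------------
# grip-force features


def grip_force_total(
    frames: Sequence[ForceFrame], threshold: float = DEFAULT_FORCE_THRESHOLD
) -> ForceFeatures:
    """Thresholded total grip force over a stack of frames (one motion, one side).

    Takes the per-cell maximum over time, zeroes cells below the effective-
    grip threshold, and sums the survivors.  Monotone non-decreasing in every
    cell value; non-increasing in the threshold.
    """
    if len(frames) == 0:
        raise ValidationError("empty force-frame set")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    mids = {(f.motion_id, f.side) for f in frames}
    if len(mids) > 1:
        raise ValidationError(f"mixed motions/sides in one frame set: {sorted(mids)}")
    peak = np.max(np.stack([f.grid for f in frames]), axis=0)
    peak = np.where(peak >= threshold, peak, 0.0)
    return ForceFeatures(total_force=float(peak.sum()), threshold=threshold, peak_grid=peak)


def mirror_force(frame: ForceFrame) -> ForceFrame:
    """Left-right flip of the grid (columns reversed), values unchanged.

    Used to overlay the healthy hand's print on the affected hand's frame of
    reference for audit displays; force sums are mirror-invariant.
    """
    return ForceFrame(
        t=frame.t, grid=frame.grid[:, ::-1].copy(), motion_id=frame.motion_id, side=frame.side
    )
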