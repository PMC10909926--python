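"""Signal conditioning: zero-phase low-pass filtering, resampling, alignment.

Raw marker trajectories carry tracking jitter and motion artefacts; before
any angle is computed, every coordinate channel is passed through a
fourth-order Butterworth low-pass at 12 Hz.  The filter is applied
forward-backward (zero phase): item scoring compares affected vs. healthy
trajectories point by point, and a one-pass filter's group delay would bias
that deviation.

Hand landmarks estimated from the colour image live in the same camera frame
as the body skeleton but on an arbitrary scale; :func:`align_hand_to_body`
pins them to the skeleton with a translation + uniform scale (rotation is
deliberately excluded — a two-point correspondence cannot determine it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .datamodel import (
    GeometryError,
    HandSample,
    HandTrack,
    JointSample,
    MotionClip,
    ValidationError,
)

__all__ = ["FilterSpec", "lowpass", "resample_to", "align_hand_to_body", "filter_clip"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass parameters. Defaults: order 4, cutoff 12 Hz."""

    fs: float
    order: int = 4
    cutoff_hz: float = 12.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, fs/2) = (0, {self.fs / 2}) Hz"
            )


def lowpass(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the first axis.

    Output has the same length; DC passes unchanged.  Requires at least
    ``3 * (order + 1) + 1`` samples for stable forward-backward padding.
    """
    x = np.asarray(x, float)
    min_len = 3 * (spec.order + 1) + 1
    if x.shape[0] < min_len:
        raise ValidationError(
            f"signal too short for zero-phase filtering: {x.shape[0]} < {min_len}"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def resample_to(x: np.ndarray, n: int) -> np.ndarray:
    """Linear interpolation onto ``n`` uniform points of [0, 1]; endpoints kept."""
    x = np.asarray(x, float)
    if n < 2:
        raise ValidationError(f"resample target length must be >= 2, got {n}")
    if x.shape[0] < 2:
        raise ValidationError("cannot resample a signal of fewer than 2 samples")
    if x.shape[0] == n:
        return x.copy()
    src = np.linspace(0.0, 1.0, x.shape[0])
    dst = np.linspace(0.0, 1.0, n)
    if x.ndim == 1:
        return np.interp(dst, src, x)
    out = np.empty((n,) + x.shape[1:], float)
    flat = x.reshape(x.shape[0], -1)
    res = np.stack([np.interp(dst, src, flat[:, j]) for j in range(flat.shape[1])], axis=1)
    return res.reshape((n,) + x.shape[1:])


def align_hand_to_body(hand: HandSample, body: JointSample, side: str) -> HandSample:
    """Similarity-align hand landmarks to the skeleton wrist -> hand-tip segment.

    Landmark 0 (hand wrist) is translated onto the body wrist; the uniform
    scale is set so the wrist->middle-fingertip distance matches the body's
    wrist->hand-tip distance.  All 21 landmarks get the same transform, so
    every angle between landmark vectors is preserved.
    """
    suffix = "_R" if side == "right" else "_L"
    body.require("WRIST" + suffix, "HANDTIP" + suffix)
    wrist_b = body.joints["WRIST" + suffix]
    tip_b = body.joints["HANDTIP" + suffix]
    lm = hand.landmarks
    seg_hand = lm[12] - lm[0]
    len_hand = float(np.linalg.norm(seg_hand))
    len_body = float(np.linalg.norm(tip_b - wrist_b))
    if len_hand < 1e-12 or len_body < 1e-12:
        raise GeometryError("degenerate wrist->fingertip segment; cannot align hand")
    s = len_body / len_hand
    aligned = wrist_b + s * (lm - lm[0])
    return HandSample(t=hand.t, landmarks=aligned)


def filter_clip(clip: MotionClip, spec: FilterSpec | None = None) -> MotionClip:
    """Low-pass every joint and hand-landmark coordinate channel of a clip."""
    if spec is None:
        spec = FilterSpec(fs=clip.fs)
    joints = {k: lowpass(v, spec) for k, v in clip.joints.items()}
    hand = None
    if clip.hand is not None:
        hand = HandTrack(
            t=clip.hand.t.copy(),
            landmarks=lowpass(
                clip.hand.landmarks.reshape(len(clip.hand), -1), spec
            ).reshape(clip.hand.landmarks.shape),
        )
    return MotionClip(
        motion_id=clip.motion_id,
        side=clip.side,
        fs=clip.fs,
        t=clip.t.copy(),
        joints=joints,
        hand=hand,
    )
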