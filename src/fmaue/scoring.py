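"""End-to-end scoring: features -> fuzzy inference -> item scores -> severity.

Pipeline per item: low-pass filter both sides' clips, compute the item's
angle traces or task features, form affected/healthy ratios, run each
sub-motion's Mamdani system, discretise the crisp output to {0, 1, 2}, and
combine multi-sub-motion items with the any-0/all-2 rule.  The total is the
sum over scorable items; items whose data is missing or degenerate are
reported in ``diagnostics`` and excluded from the total rather than scored 0.

Severity bands (severe < 32 <= moderate <= 57 < mild <= 66) are published
for the 66-point clinical scale; the automated total spans 30 items x 2 = 60
points.  By default the bands are applied to the raw total (with that caveat
documented); an optional rescale by 66/60 can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel import AssessmentReport, MotionClip, Recording, ValidationError
from .features import (
    DEFAULT_DEVIATION_SAMPLES,
    DEFAULT_FORCE_THRESHOLD,
    ReachFeatures,
    angle_ratio_features,
    clip_universe,
    finger_nose_features,
    grip_force_total,
    hand_hip_ratio,
    mean_velocity,
)
from .fuzzy import combine_subscores, discretise, mamdani_score
from .kinematics import angle_traces
from .preprocess import FilterSpec, filter_clip
from .registry import ItemSpec, SeverityThresholds, SubMotionSpec, build_registry

__all__ = [
    "ItemScore",
    "classify_severity",
    "item_features",
    "score_item",
    "assess",
]


@dataclass
class ItemScore:
    value: int
    crisp: list[float]
    sub_scores: list[int]
    features: list[dict[str, float]]


def classify_severity(
    total: int, thresholds: SeverityThresholds = SeverityThresholds()
) -> str:
    """Severity class from a total score: <32 severe, 32-57 moderate, 58+ mild."""
    if not 0 <= total <= thresholds.mild_upper:
        raise ValidationError(
            f"total {total} outside [0, {thresholds.mild_upper}]"
        )
    if total < thresholds.severe_below:
        return "severe"
    if total <= thresholds.moderate_upper:
        return "moderate"
    return "mild"


class _Session:
    """Per-recording caches: filtered clips and finger-nose features."""

    def __init__(self, recording: Recording, deviation_samples: int, force_threshold: float):
        self.recording = recording
        self.deviation_samples = deviation_samples
        self.force_threshold = force_threshold
        self._filtered: dict[tuple[str, str], MotionClip] = {}
        self._reach: dict[tuple[str, str], ReachFeatures] = {}

    def clip(self, motion_id: str, side: str) -> MotionClip:
        key = (motion_id, side)
        if key not in self._filtered:
            raw = self.recording.clip(motion_id, side)
            self._filtered[key] = filter_clip(raw, FilterSpec(fs=raw.fs))
        return self._filtered[key]

    def reach(self, motion_id: str, side: str) -> ReachFeatures:
        key = (motion_id, side)
        if key not in self._reach:
            self._reach[key] = finger_nose_features(self.clip(motion_id, side))
        return self._reach[key]


def _ratio(num: float, den: float, what: str) -> float:
    if den <= 0:
        raise ValidationError(f"uninformative healthy reference for {what} (denominator {den:.3g})")
    return clip_universe(num / den)


def _sub_motion_features(session: _Session, sm: SubMotionSpec) -> dict[str, float]:
    mid = sm.motion_id
    if sm.kind == "angle":
        aff = session.clip(mid, "affected")
        hea = session.clip(mid, "healthy")
        label = sm.angle
        ta = angle_traces(aff, [label])[label]
        th = angle_traces(hea, [label])[label]
        return angle_ratio_features(ta, th, session.deviation_samples)
    if sm.kind == "reach_alpha":
        alphas = {}
        for side in ("affected", "healthy"):
            alphas[side] = hand_hip_ratio(session.clip(mid, side))
        completion = {s: max(0.0, 1.0 - a) for s, a in alphas.items()}
        return {
            "alpha_completion_ratio": _ratio(
                completion["affected"], completion["healthy"], "hand-hip completion"
            )
        }
    if sm.kind == "finger":
        label = "finger_bend_thumb" if sm.finger == "thumb" else "finger_bend_four_mean"
        exc = {}
        mv = {}
        for side in ("affected", "healthy"):
            tr = angle_traces(session.clip(mid, side), [label])[label]
            exc[side] = float(np.max(np.abs(tr.value - tr.value[0])))
            mv[side] = mean_velocity(tr)
        return {
            "angle_ratio": _ratio(exc["affected"], exc["healthy"], f"{label} excursion"),
            "mv_ratio": _ratio(mv["affected"], mv["healthy"], f"{label} velocity"),
        }
    if sm.kind == "grip":
        totals = {}
        for side in ("affected", "healthy"):
            frames = session.recording.frames(mid, side)
            totals[side] = grip_force_total(frames, session.force_threshold).total_force
        return {"force_ratio": _ratio(totals["affected"], totals["healthy"], f"{mid} grip force")}
    if sm.kind == "tremor":
        a = session.reach(mid, "affected")
        h = session.reach(mid, "healthy")
        ma_ratio = a.mean_accel / h.mean_accel if h.mean_accel > 0 else np.inf
        return {
            "mv_ratio": _ratio(a.mean_speed, h.mean_speed, "fingertip speed"),
            "ma_dev": clip_universe(abs(ma_ratio - 1.0)),
        }
    if sm.kind == "dysmetria":
        a = session.reach(mid, "affected")
        h = session.reach(mid, "healthy")
        ca, ch = max(0.0, 1.0 - a.gamma), max(0.0, 1.0 - h.gamma)
        beta_ratio = a.beta / h.beta if h.beta > 0 else np.inf
        return {
            "gamma_ratio": _ratio(ca, ch, "finger-nose completion"),
            "beta_dev": clip_universe(abs(beta_ratio - 1.0)),
        }
    if sm.kind == "speed":
        a = session.reach(mid, "affected")
        h = session.reach(mid, "healthy")
        return {"vmax_ratio": _ratio(a.vmax, h.vmax, "fingertip peak speed")}
    raise ValidationError(f"unknown sub-motion kind {sm.kind!r}")


def item_features(
    recording: Recording,
    item: ItemSpec,
    deviation_samples: int = DEFAULT_DEVIATION_SAMPLES,
    force_threshold: float = DEFAULT_FORCE_THRESHOLD,
) -> list[dict[str, float]]:
    """Fuzzy input values for every sub-motion of one item."""
    session = _Session(recording, deviation_samples, force_threshold)
    return [_sub_motion_features(session, sm) for sm in item.sub_motions]


def score_item(item: ItemSpec, features: Sequence[Mapping[str, float]]) -> ItemScore:
    """Score one item from its per-sub-motion fuzzy inputs."""
    if len(features) != len(item.sub_motions):
        raise ValidationError(
            f"item {item.item_id}: expected {len(item.sub_motions)} feature sets, "
            f"got {len(features)}"
        )
    crisp = []
    subs = []
    for fis, feats in zip(item.sub_fis, features):
        res = mamdani_score(fis, feats)
        crisp.append(res.crisp)
        subs.append(discretise(res.crisp))
    return ItemScore(
        value=combine_subscores(subs),
        crisp=crisp,
        sub_scores=subs,
        features=[dict(f) for f in features],
    )


def assess(
    recording: Recording,
    registry: Optional[Sequence[ItemSpec]] = None,
    *,
    deviation_samples: int = DEFAULT_DEVIATION_SAMPLES,
    force_threshold: float = DEFAULT_FORCE_THRESHOLD,
    thresholds: SeverityThresholds = SeverityThresholds(),
    rescale_total: bool = False,
) -> AssessmentReport:
    """Score a full recording: 30 items, total, severity class.

    Items whose inputs are missing or degenerate are listed in
    ``diagnostics`` and excluded from the total (never silently zeroed).
    With ``rescale_total`` the severity bands are applied to
    ``total * 66/60`` to compensate the 60- vs 66-point span.
    """
    if registry is None:
        registry = build_registry()
    session = _Session(recording, deviation_samples, force_threshold)
    item_scores: dict[int, int] = {}
    feats_audit: dict[int, list[dict[str, float]]] = {}
    sub_audit: dict[int, list[int]] = {}
    diagnostics: list[str] = []
    for item in registry:
        try:
            feats = [_sub_motion_features(session, sm) for sm in item.sub_motions]
            scored = score_item(item, feats)
        except (ValidationError, KeyError) as exc:
            diagnostics.append(f"item {item.item_id} ({item.feature_symbol}) unscorable: {exc}")
            continue
        item_scores[item.item_id] = scored.value
        feats_audit[item.item_id] = scored.features
        sub_audit[item.item_id] = scored.sub_scores
    total = int(sum(item_scores.values()))
    graded = total * 66.0 / 60.0 if rescale_total else total
    severity = classify_severity(int(round(graded)), thresholds)
    return AssessmentReport(
        subject_id=recording.subject_id,
        item_scores=item_scores,
        total=total,
        severity=severity,
        features=feats_audit,
        sub_scores=sub_audit,
        diagnostics=diagnostics,
    )
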