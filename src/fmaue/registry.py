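"""The 30-item scoring registry.

The upper-extremity scale has 33 items; the two reflex items and one other
manual item are not automatable without a reflex hammer, leaving 30 items
(feature symbols F1-F30) measured through 21 motion sets M1-M21:

* M1 / M2 — flexor / extensor synergy composites, each yielding several
  joint-angle items scored from ROM, MV and deviation SD ratios;
* M3 — hand to lumbar spine (hand-hip length ratio alpha);
* M4-M13 — isolated arm / wrist sub-motions entering multi-FIS items;
* M14 / M15 — mass finger flexion / extension (bend-angle + MV ratios,
  thumb and four-finger-mean sub-FIS);
* M16-M20 — hook / lateral-pinch / pincer / cylinder / sphere grasps on the
  pressure grid (thresholded force-sum ratios);
* M21 — finger-nose test (tremor, dysmetria, speed items).

Each sub-motion gets its own fuzzy system; multi-sub-motion items combine
sub-scores with the any-0 -> 0 / all-2 -> 2 rule.  Per-item membership
functions, universes and rules are overridable through a config mapping
without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from .datamodel import ValidationError
from .fuzzy import DEFAULT_RESOLUTION, FisSpec, default_fis

__all__ = [
    "SubMotionSpec",
    "ItemSpec",
    "SeverityThresholds",
    "build_registry",
    "registry_table",
]


@dataclass(frozen=True)
class SubMotionSpec:
    """One sub-motion of an item: which clip, which feature recipe.

    ``kind`` selects the fuzzy inputs:

    ============  =======================================================
    angle         rom_ratio, mv_ratio (incr) + sd_norm (decr) of ``angle``
    reach_alpha   hand-hip completion ratio (incr)
    finger        bend-angle excursion ratio + mv_ratio (incr), ``finger``
    grip          thresholded force-sum ratio (incr)
    tremor        fingertip mv_ratio (incr) + |MA ratio - 1| (decr)
    dysmetria     gamma completion ratio (incr) + |beta ratio - 1| (decr)
    speed         fingertip peak-speed ratio (incr)
    ============  =======================================================
    """

    motion_id: str
    kind: str
    angle: Optional[str] = None
    finger: Optional[str] = None


@dataclass(frozen=True)
class ItemSpec:
    item_id: int  # published item number (3..17, 19..33)
    feature_symbol: str  # F1..F30
    name: str
    sub_motions: tuple[SubMotionSpec, ...]
    sub_fis: tuple[FisSpec, ...]
    max_points: int = 2

    def __post_init__(self) -> None:
        if len(self.sub_fis) != len(self.sub_motions):
            raise ValidationError(
                f"item {self.item_id}: one FIS per sub-motion required"
            )


@dataclass(frozen=True)
class SeverityThresholds:
    """Published severity bands on the total score: < 32 severe,
    32-57 moderate, 58-66 mild."""

    severe_below: int = 32
    moderate_upper: int = 57
    mild_upper: int = 66

    def __post_init__(self) -> None:
        if not self.severe_below <= self.moderate_upper <= self.mild_upper:
            raise ValidationError("severity thresholds must be ordered")


_KIND_INPUTS: dict[str, tuple[tuple[str, str], ...]] = {
    "angle": (
        ("rom_ratio", "increasing"),
        ("mv_ratio", "increasing"),
        ("sd_norm", "decreasing"),
    ),
    "reach_alpha": (("alpha_completion_ratio", "increasing"),),
    "finger": (("angle_ratio", "increasing"), ("mv_ratio", "increasing")),
    "grip": (("force_ratio", "increasing"),),
    "tremor": (("mv_ratio", "increasing"), ("ma_dev", "decreasing")),
    "dysmetria": (("gamma_ratio", "increasing"), ("beta_dev", "decreasing")),
    "speed": (("vmax_ratio", "increasing"),),
}


def _sm(motion_id: str, kind: str, angle: str | None = None, finger: str | None = None):
    return SubMotionSpec(motion_id=motion_id, kind=kind, angle=angle, finger=finger)


# item_id, feature symbol, name, sub-motion specs
_TABLE: tuple[tuple[int, str, str, tuple[SubMotionSpec, ...]], ...] = (
    # flexor synergy (one composite clip, one angle per item)
    (3, "F1", "Shoulder elevation", (_sm("M1", "angle", "shoulder_elevation"),)),
    (4, "F2", "Shoulder retraction", (_sm("M1", "angle", "shoulder_retraction"),)),
    (5, "F3", "Shoulder abduction (>=90 deg)", (_sm("M1", "angle", "shoulder_abduction"),)),
    (6, "F4", "Shoulder external rotation", (_sm("M1", "angle", "shoulder_external_rotation"),)),
    (7, "F5", "Elbow flexion", (_sm("M1", "angle", "elbow_flexion"),)),
    (8, "F6", "Forearm supination", (_sm("M1", "angle", "forearm_supination"),)),
    # extensor synergy
    (9, "F7", "Shoulder adduction/internal rotation", (_sm("M2", "angle", "shoulder_internal_rotation"),)),
    (10, "F8", "Elbow extension", (_sm("M2", "angle", "elbow_extension"),)),
    (11, "F9", "Forearm pronation", (_sm("M2", "angle", "forearm_pronation"),)),
    # mixing synergies
    (12, "F10", "Hand to lumbar spine", (_sm("M3", "reach_alpha"),)),
    (13, "F11", "Shoulder flexion 0-90, elbow extended",
     (_sm("M4", "angle", "shoulder_flexion"), _sm("M5", "angle", "elbow_flexion"))),
    (14, "F12", "Forearm pronation/supination, elbow 90, shoulder 0",
     (_sm("M6", "angle", "forearm_pronation"), _sm("M7", "angle", "elbow_flexion"),
      _sm("M8", "angle", "forearm_supination"))),
    # little or no synergy
    (15, "F13", "Shoulder abduction 0-90, elbow extended, forearm pronated",
     (_sm("M9", "angle", "shoulder_abduction"), _sm("M5", "angle", "elbow_flexion"),
      _sm("M6", "angle", "forearm_pronation"))),
    (16, "F14", "Shoulder flexion 90-180, elbow extended",
     (_sm("M10", "angle", "shoulder_flexion"), _sm("M5", "angle", "elbow_flexion"))),
    (17, "F15", "Forearm pronation/supination, elbow extended, shoulder 30-90",
     (_sm("M5", "angle", "elbow_flexion"), _sm("M6", "angle", "forearm_pronation"),
      _sm("M11", "angle", "shoulder_flexion"))),
    # wrist
    (19, "F16", "Wrist stability at 15 deg dorsiflexion, elbow 90",
     (_sm("M12", "angle", "wrist_dorsiflexion"), _sm("M7", "angle", "elbow_flexion"),
      _sm("M8", "angle", "forearm_supination"))),
    (20, "F17", "Repeated wrist flexion/extension, elbow 90",
     (_sm("M13", "angle", "wrist_flexion"), _sm("M7", "angle", "elbow_flexion"))),
    (21, "F18", "Wrist stability at 15 deg dorsiflexion, elbow 0, shoulder 30",
     (_sm("M12", "angle", "wrist_dorsiflexion"), _sm("M5", "angle", "elbow_flexion"),
      _sm("M11", "angle", "shoulder_flexion"))),
    (22, "F19", "Repeated wrist flexion/extension, elbow 0, shoulder 30",
     (_sm("M12", "angle", "wrist_dorsiflexion"), _sm("M5", "angle", "elbow_flexion"),
      _sm("M11", "angle", "shoulder_flexion"))),
    (23, "F20", "Wrist circumduction",
     (_sm("M13", "angle", "wrist_flexion"), _sm("M5", "angle", "elbow_flexion"),
      _sm("M11", "angle", "shoulder_flexion"))),
    # hand
    (24, "F21", "Mass flexion",
     (_sm("M14", "finger", finger="thumb"), _sm("M14", "finger", finger="four_mean"))),
    (25, "F22", "Mass extension",
     (_sm("M15", "finger", finger="thumb"), _sm("M15", "finger", finger="four_mean"))),
    (26, "F23", "Hook grasp", (_sm("M16", "grip"),)),
    (27, "F24", "Lateral pinch", (_sm("M17", "grip"),)),
    (28, "F25", "Pincer grasp", (_sm("M18", "grip"),)),
    (29, "F26", "Cylinder grasp", (_sm("M19", "grip"),)),
    (30, "F27", "Sphere grasp", (_sm("M20", "grip"),)),
    # coordination / speed (one clip, three items)
    (31, "F28", "Finger-nose tremor", (_sm("M21", "tremor"),)),
    (32, "F29", "Finger-nose dysmetria", (_sm("M21", "dysmetria"),)),
    (33, "F30", "Finger-nose speed", (_sm("M21", "speed"),)),
)


def registry_table() -> list[dict]:
    """Machine-readable item -> motions/features mapping (for audit and docs)."""
    return [
        {
            "item_id": item_id,
            "feature_symbol": symbol,
            "name": name,
            "sub_motions": [
                {k: v for k, v in
                 (("motion_id", sm.motion_id), ("kind", sm.kind),
                  ("angle", sm.angle), ("finger", sm.finger)) if v is not None}
                for sm in subs
            ],
            "fis_inputs": [[n for n, _ in _KIND_INPUTS[sm.kind]] for sm in subs],
        }
        for item_id, symbol, name, subs in _TABLE
    ]


def build_registry(
    config: Optional[Mapping] = None, resolution: int = DEFAULT_RESOLUTION
) -> list[ItemSpec]:
    """Build the 30 item specs with default fuzzy systems.

    ``config`` may override per-item fuzzy systems: a mapping from item id
    (int or str) to either a full FIS dict (see :meth:`FisSpec.to_dict`)
    applied to every sub-motion, or ``{"sub_fis": [fis_dict, ...]}`` with one
    entry per sub-motion.  A path-like pointing at a JSON file is accepted.
    Unknown item ids raise.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text(encoding="utf-8"))
    overrides = {int(k): v for k, v in (config or {}).items()}
    known = {item_id for item_id, *_ in _TABLE}
    unknown = set(overrides) - known
    if unknown:
        raise ValidationError(f"config overrides unknown items: {sorted(unknown)}")

    registry = []
    for item_id, symbol, name, subs in _TABLE:
        ov = overrides.get(item_id)
        sub_fis = []
        for j, sm in enumerate(subs):
            if ov is not None:
                fis_dict = ov["sub_fis"][j] if "sub_fis" in ov else ov
                sub_fis.append(FisSpec.from_dict(fis_dict))
            else:
                names = [n for n, _ in _KIND_INPUTS[sm.kind]]
                dirs = [d for _, d in _KIND_INPUTS[sm.kind]]
                sub_fis.append(default_fis(names, dirs, resolution=resolution))
        registry.append(
            ItemSpec(
                item_id=item_id,
                feature_symbol=symbol,
                name=name,
                sub_motions=subs,
                sub_fis=tuple(sub_fis),
            )
        )
    return registry
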