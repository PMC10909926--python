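"""Mamdani fuzzy inference for item scoring.

Each item (or sub-motion) is scored by a small Mamdani fuzzy inference
system: every input is covered by three trapezoidal membership functions
(low / medium / high), the output score in [0, 2] by three triangular ones.
Rule firing uses the min t-norm; the fired output sets are combined and the
crisp score is the centroid of the aggregate on a uniform discretisation of
[0, 2].

Two implication/aggregation pairs are supported.  The default is the
additive variant — product (scaling) implication with sum aggregation —
because scaling preserves each output set's centroid, which makes the crisp
score a weighted average of the label centroids (1/3, 1, 5/3) and hence
exactly monotone in every oriented input for the generated rule bases.  The
clipping variant (min implication, max aggregation) is available per
config; it produces the same scores on the membership plateaus but shows
small non-monotone centroid ripples (~0.06) where input labels cross over,
an inherent artefact of clipped-set centroids.

Trapezoid (knots a <= b <= c <= d):

    f(x) = 0 for x <= a; (x-a)/(b-a) on [a,b]; 1 on [b,c];
           (d-x)/(d-c) on [c,d]; 0 for x >= d

Triangle (knots e <= f <= g): rises on [e,f], peaks at f, falls on [f,g].
Degenerate edges (a=b, c=d, e=f, f=g) are crisp steps with membership 1 at
the shared knot.

The default parameters — inputs low [-0.4,-0.1,0.1,0.4], medium
[0.1,0.4,0.6,0.9], high [0.6,0.9,1.1,1.4] on the [0,1] ratio domain (the
outer knots extend past the domain so its edges sit on full plateaus),
outputs [0,0,1], [0,1,2], [1,2,2] on [0,2] — form a partition of unity on
the input universe and are applied to every item unless a per-item override
is configured.

Rule bases are generated, not hand-enumerated: each input label maps to an
ordinal level 0/1/2 (inverted for "decreasing" inputs, where a low raw value
is the good outcome, e.g. the deviation SD), and the consequent is the
minimum oriented level — the weakest link decides, matching the clinical
reading that any failing aspect caps the score.

Final item scores combine sub-motion scores with the published rule:
0 if any sub-motion scored 0, 2 if all scored 2, else 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import ValidationError

__all__ = [
    "TrapezoidMF",
    "TriangleMF",
    "FuzzyInput",
    "FuzzyOutput",
    "Rule",
    "FisSpec",
    "MamdaniResult",
    "trapezoid_membership",
    "triangle_membership",
    "mamdani_score",
    "discretise",
    "combine_subscores",
    "default_rule_base",
    "default_input_mfs",
    "default_output_mfs",
    "default_fis",
]

LABELS = ("low", "medium", "high")
_LEVEL_TO_LABEL = {0: "low", 1: "medium", 2: "high"}

#: Default defuzzification grid resolution on [0, 2].
DEFAULT_RESOLUTION = 2001


@dataclass(frozen=True)
class TrapezoidMF:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValidationError(f"trapezoid knots must be ordered: {self}")

    @property
    def knots(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class TriangleMF:
    e: float
    f: float
    g: float

    def __post_init__(self) -> None:
        if not (self.e <= self.f <= self.g):
            raise ValidationError(f"triangle knots must be ordered: {self}")

    @property
    def knots(self) -> tuple[float, float, float]:
        return (self.e, self.f, self.g)


def trapezoid_membership(x, mf: TrapezoidMF):
    """Piecewise-linear trapezoidal membership in [0, 1].

    Plateau membership is evaluated first so that degenerate vertical edges
    (a = b or c = d) behave as crisp steps including the edge point; for
    non-degenerate knots the boundary values are f(a) = f(d) = 0.
    """
    x = np.asarray(x, float)
    scalar = x.ndim == 0
    if scalar:
        x = x[None]
    a, b, c, d = mf.knots
    y = np.zeros_like(x)
    if b > a:
        m = (x > a) & (x < b)
        y[m] = (x[m] - a) / (b - a)
    if d > c:
        m = (x > c) & (x < d)
        y[m] = (d - x[m]) / (d - c)
    y[(x >= b) & (x <= c)] = 1.0
    return float(y[0]) if scalar else y


def triangle_membership(x, mf: TriangleMF):
    """Piecewise-linear triangular membership in [0, 1]; peak at the f knot.

    Degenerate shoulders (e = f or f = g) are right-angle triangles with
    membership 1 at the shared knot.
    """
    x = np.asarray(x, float)
    scalar = x.ndim == 0
    if scalar:
        x = x[None]
    e, f, g = mf.knots
    y = np.zeros_like(x)
    if f > e:
        m = (x > e) & (x < f)
        y[m] = (x[m] - e) / (f - e)
    if g > f:
        m = (x > f) & (x < g)
        y[m] = (g - x[m]) / (g - f)
    y[x == f] = 1.0
    return float(y[0]) if scalar else y


@dataclass(frozen=True)
class FuzzyInput:
    """One FIS input: name, universe, three labelled trapezoids, direction.

    ``direction`` states how the raw value relates to performance:
    "increasing" (larger is better, e.g. AROM/HROM) or "decreasing"
    (smaller is better, e.g. the normalised deviation SD).  It is consumed
    when generating the rule base, not during inference.
    """

    name: str
    universe: tuple[float, float] = (0.0, 1.0)
    mfs: Mapping[str, TrapezoidMF] = None  # type: ignore[assignment]
    direction: str = "increasing"

    def __post_init__(self) -> None:
        if self.mfs is None:
            object.__setattr__(self, "mfs", default_input_mfs())
        if set(self.mfs) != set(LABELS):
            raise ValidationError(f"input {self.name}: labels must be {LABELS}")
        if self.direction not in ("increasing", "decreasing"):
            raise ValidationError(f"input {self.name}: unknown direction {self.direction!r}")
        lo, hi = self.universe
        if not lo < hi:
            raise ValidationError(f"input {self.name}: empty universe")
        # no zero-membership gaps inside the universe
        grid = np.linspace(lo, hi, 257)
        cover = np.zeros_like(grid)
        for mf in self.mfs.values():
            cover = np.maximum(cover, trapezoid_membership(grid, mf))
        if np.any(cover <= 0):
            raise ValidationError(f"input {self.name}: membership gap inside universe")


@dataclass(frozen=True)
class FuzzyOutput:
    universe: tuple[float, float] = (0.0, 2.0)
    mfs: Mapping[str, TriangleMF] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mfs is None:
            object.__setattr__(self, "mfs", default_output_mfs())
        if set(self.mfs) != set(LABELS):
            raise ValidationError(f"output labels must be {LABELS}")


@dataclass(frozen=True)
class Rule:
    """Antecedent label per input (in input order) -> output label."""

    antecedents: tuple[str, ...]
    consequent: str


@dataclass(frozen=True)
class FisSpec:
    """A complete single-output Mamdani system for one sub-motion."""

    inputs: tuple[FuzzyInput, ...]
    output: FuzzyOutput = field(default_factory=FuzzyOutput)
    rules: tuple[Rule, ...] = ()
    resolution: int = DEFAULT_RESOLUTION
    implication: str = "prod"  # "prod" (scale) | "min" (clip)
    aggregation: str = "sum"  # "sum" (additive) | "max" (union)

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValidationError("FIS needs at least one input")
        if self.implication not in ("prod", "min"):
            raise ValidationError(f"unknown implication {self.implication!r}")
        if self.aggregation not in ("sum", "max"):
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")
        rules = self.rules
        if not rules:
            rules = tuple(default_rule_base(len(self.inputs), [i.direction for i in self.inputs]))
            object.__setattr__(self, "rules", rules)
        seen = set()
        for r in rules:
            if len(r.antecedents) != len(self.inputs):
                raise ValidationError(f"rule {r}: antecedent arity mismatch")
            for lbl in r.antecedents + (r.consequent,):
                if lbl not in LABELS:
                    raise ValidationError(f"rule {r}: unknown label {lbl!r}")
            seen.add(r.antecedents)
        if len(seen) != len(LABELS) ** len(self.inputs) or len(rules) != len(seen):
            raise ValidationError(
                "rule base must cover every input label combination exactly once"
            )
        if self.resolution < 3:
            raise ValidationError("resolution must be >= 3")

    # -- config (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "inputs": [
                {
                    "name": i.name,
                    "universe": list(i.universe),
                    "direction": i.direction,
                    "mfs": {k: list(v.knots) for k, v in i.mfs.items()},
                }
                for i in self.inputs
            ],
            "output": {
                "universe": list(self.output.universe),
                "mfs": {k: list(v.knots) for k, v in self.output.mfs.items()},
            },
            "rules": [
                {"if": list(r.antecedents), "then": r.consequent} for r in self.rules
            ],
            "resolution": self.resolution,
            "implication": self.implication,
            "aggregation": self.aggregation,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FisSpec":
        inputs = tuple(
            FuzzyInput(
                name=i["name"],
                universe=tuple(i.get("universe", (0.0, 1.0))),
                mfs={k: TrapezoidMF(*v) for k, v in i["mfs"].items()} if "mfs" in i else None,
                direction=i.get("direction", "increasing"),
            )
            for i in d["inputs"]
        )
        out = d.get("output", {})
        output = FuzzyOutput(
            universe=tuple(out.get("universe", (0.0, 2.0))),
            mfs={k: TriangleMF(*v) for k, v in out["mfs"].items()} if "mfs" in out else None,
        )
        rules = tuple(
            Rule(antecedents=tuple(r["if"]), consequent=r["then"])
            for r in d.get("rules", [])
        )
        return cls(
            inputs=inputs,
            output=output,
            rules=rules,
            resolution=int(d.get("resolution", DEFAULT_RESOLUTION)),
            implication=d.get("implication", "prod"),
            aggregation=d.get("aggregation", "sum"),
        )


@dataclass
class MamdaniResult:
    crisp: float
    label_strengths: dict[str, float]
    rule_strengths: list[float]
    empty_aggregate: bool = False


def default_input_mfs() -> dict[str, TrapezoidMF]:
    return {
        "low": TrapezoidMF(-0.4, -0.1, 0.1, 0.4),
        "medium": TrapezoidMF(0.1, 0.4, 0.6, 0.9),
        "high": TrapezoidMF(0.6, 0.9, 1.1, 1.4),
    }


def default_output_mfs() -> dict[str, TriangleMF]:
    return {
        "low": TriangleMF(0.0, 0.0, 1.0),
        "medium": TriangleMF(0.0, 1.0, 2.0),
        "high": TriangleMF(1.0, 2.0, 2.0),
    }


def default_rule_base(k_inputs: int, directions: Sequence[str]) -> list[Rule]:
    """Complete 3^k rule base: consequent = min oriented level of the inputs.

    Increasing inputs map low/medium/high to levels 0/1/2; decreasing inputs
    are inverted (low -> 2).  The minimum makes the score monotone in every
    oriented input by construction.
    """
    if k_inputs < 1:
        raise ValidationError("rule base needs at least one input")
    if len(directions) != k_inputs:
        raise ValidationError("one direction per input required")
    for d in directions:
        if d not in ("increasing", "decreasing"):
            raise ValidationError(f"unknown direction {d!r}")
    rules = []
    for combo in np.ndindex(*([len(LABELS)] * k_inputs)):
        levels = [
            idx if direction == "increasing" else 2 - idx
            for idx, direction in zip(combo, directions)
        ]
        rules.append(
            Rule(
                antecedents=tuple(LABELS[i] for i in combo),
                consequent=_LEVEL_TO_LABEL[min(levels)],
            )
        )
    return rules


def mamdani_score(fis: FisSpec, inputs: Mapping[str, float]) -> MamdaniResult:
    """Run Mamdani inference (min firing, configurable implication and
    aggregation) and centroid-defuzzify.

    Inputs are clipped to their universes.  If no rule fires at all (possible
    only with non-default membership configurations leaving gaps), the
    midpoint of the output universe is returned with ``empty_aggregate`` set.
    """
    x = []
    for inp in fis.inputs:
        if inp.name not in inputs:
            raise ValidationError(f"missing FIS input {inp.name!r}")
        v = float(inputs[inp.name])
        if not np.isfinite(v):
            raise ValidationError(f"FIS input {inp.name!r} is not finite")
        x.append(float(np.clip(v, *inp.universe)))

    memberships = [
        {lbl: float(trapezoid_membership(xi, inp.mfs[lbl])) for lbl in LABELS}
        for inp, xi in zip(fis.inputs, x)
    ]
    label_strengths = {lbl: 0.0 for lbl in LABELS}
    rule_strengths = []
    for rule in fis.rules:
        strength = min(m[lbl] for m, lbl in zip(memberships, rule.antecedents))
        rule_strengths.append(strength)
        if strength > label_strengths[rule.consequent]:
            label_strengths[rule.consequent] = strength

    lo, hi = fis.output.universe
    y = np.linspace(lo, hi, fis.resolution)
    agg = np.zeros_like(y)
    for lbl, s in label_strengths.items():
        if s > 0:
            mf_y = triangle_membership(y, fis.output.mfs[lbl])
            fired = s * mf_y if fis.implication == "prod" else np.minimum(s, mf_y)
            agg = agg + fired if fis.aggregation == "sum" else np.maximum(agg, fired)
    area = np.trapezoid(agg, y)
    if area <= 1e-12:
        return MamdaniResult(
            crisp=0.5 * (lo + hi),
            label_strengths=label_strengths,
            rule_strengths=rule_strengths,
            empty_aggregate=True,
        )
    crisp = float(np.trapezoid(agg * y, y) / area)
    return MamdaniResult(
        crisp=crisp, label_strengths=label_strengths, rule_strengths=rule_strengths
    )


def discretise(crisp: float) -> int:
    """Crisp score in [0, 2] -> nearest integer; half points round down."""
    if not 0.0 <= crisp <= 2.0:
        raise ValidationError(f"crisp score {crisp} outside [0, 2]")
    return int(np.ceil(crisp - 0.5))


def combine_subscores(scores: Sequence[int]) -> int:
    """Combine sub-motion scores: any 0 -> 0; all 2 -> 2; otherwise 1."""
    if len(scores) == 0:
        raise ValidationError("cannot combine an empty score list")
    for s in scores:
        if s not in (0, 1, 2):
            raise ValidationError(f"sub-score {s!r} outside {{0,1,2}}")
    if any(s == 0 for s in scores):
        return 0
    if all(s == 2 for s in scores):
        return 2
    return 1


def default_fis(
    names: Sequence[str],
    directions: Sequence[str] | None = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> FisSpec:
    """Build a FIS with the default membership functions and generated rules."""
    if directions is None:
        directions = ["increasing"] * len(names)
    inputs = tuple(
        FuzzyInput(name=n, direction=d) for n, d in zip(names, directions)
    )
    return FisSpec(inputs=inputs, resolution=resolution)
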