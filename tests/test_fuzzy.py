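"""Membership functions, Mamdani inference, score combination."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmaue.datamodel import ValidationError
from fmaue.fuzzy import (
    FisSpec,
    FuzzyInput,
    Rule,
    TrapezoidMF,
    TriangleMF,
    combine_subscores,
    default_fis,
    default_input_mfs,
    default_rule_base,
    discretise,
    mamdani_score,
    trapezoid_membership,
    triangle_membership,
)

LOW = TrapezoidMF(-0.4, -0.1, 0.1, 0.4)
MED = TrapezoidMF(0.1, 0.4, 0.6, 0.9)
HIGH = TrapezoidMF(0.6, 0.9, 1.1, 1.4)
OUT_LOW = TriangleMF(0, 0, 1)
OUT_MED = TriangleMF(0, 1, 2)
OUT_HIGH = TriangleMF(1, 2, 2)


class TestMemberships:
    @pytest.mark.parametrize(
        "x,mf,expected",
        [
            # plateau, ramps and boundaries of the published parameter vectors
            (0.5, MED, 1.0),
            (0.25, MED, 0.5),  # (0.25-0.1)/(0.4-0.1)
            (0.1, MED, 0.0),
            (0.9, MED, 0.0),
            (0.75, MED, 0.5),  # falling edge (0.9-0.75)/0.3
            (0.0, LOW, 1.0),
            (0.4, LOW, 0.0),
            (0.25, LOW, 0.5),
            (1.0, HIGH, 1.0),
            (0.6, HIGH, 0.0),
            (0.75, HIGH, 0.5),
            (1.4, HIGH, 0.0),
        ],
    )
    def test_trapezoid_printed_parameters(self, x, mf, expected):
        assert trapezoid_membership(x, mf) == pytest.approx(expected, abs=1e-12)

    def test_trapezoid_degenerate_edge_is_crisp_step(self):
        step = TrapezoidMF(0.0, 0.0, 1.0, 2.0)
        assert trapezoid_membership(0.0, step) == 1.0
        assert trapezoid_membership(-1e-9, step) == 0.0

    @pytest.mark.parametrize(
        "x,mf,expected",
        [
            (1.0, OUT_MED, 1.0),
            (0.5, OUT_MED, 0.5),
            (0.0, OUT_MED, 0.0),
            (2.0, OUT_MED, 0.0),
            (2.0, OUT_HIGH, 1.0),  # right-shoulder convention
            (1.5, OUT_HIGH, 0.5),
            (0.0, OUT_LOW, 1.0),
            (0.5, OUT_LOW, 0.5),
        ],
    )
    def test_triangle_printed_parameters(self, x, mf, expected):
        assert triangle_membership(x, mf) == pytest.approx(expected, abs=1e-12)

    def test_ordering_enforced(self):
        with pytest.raises(ValidationError):
            TrapezoidMF(1, 0, 2, 3)
        with pytest.raises(ValidationError):
            TriangleMF(2, 1, 3)

    def test_default_inputs_partition_of_unity_on_domain(self):
        mfs = default_input_mfs()
        x = np.linspace(0, 1, 201)
        total = sum(trapezoid_membership(x, mf) for mf in mfs.values())
        assert np.allclose(total, 1.0)


class TestMamdani:
    def test_single_high_rule_matches_closed_form_centroid(self):
        # high plateau input fires only the high output MF at strength 1;
        # centroid of the [1,2,2] triangle is 5/3
        fis = default_fis(["x"])
        res = mamdani_score(fis, {"x": 1.0})
        assert res.label_strengths == {"low": 0.0, "medium": 0.0, "high": 1.0}
        assert res.crisp == pytest.approx(5.0 / 3.0, abs=1e-6)

    def test_single_medium_rule_symmetric_centroid(self):
        fis = default_fis(["x"])
        res = mamdani_score(fis, {"x": 0.5})
        assert res.label_strengths["medium"] == 1.0
        assert res.crisp == pytest.approx(1.0, abs=1e-9)

    def test_low_only_matches_closed_form(self):
        # centroid of the [0,0,1] triangle is 1/3
        fis = default_fis(["x"])
        res = mamdani_score(fis, {"x": 0.0})
        assert res.crisp == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_equal_low_high_strengths_balance_to_midpoint(self):
        fis = FisSpec(
            inputs=(FuzzyInput(name="x"),),
            rules=(
                Rule(("low",), "high"),
                Rule(("medium",), "low"),
                Rule(("high",), "low"),
            ),
        )
        # x = 0.25: low and medium both fire at 0.5 -> high and low clipped
        # equally; the aggregate is symmetric about 1
        res = mamdani_score(fis, {"x": 0.25})
        assert res.crisp == pytest.approx(1.0, abs=1e-9)

    def test_nan_input_rejected(self):
        fis = default_fis(["x"])
        with pytest.raises(ValidationError):
            mamdani_score(fis, {"x": float("nan")})

    def test_inputs_clipped_to_universe(self):
        fis = default_fis(["x"])
        assert mamdani_score(fis, {"x": 7.0}).crisp == mamdani_score(fis, {"x": 1.0}).crisp
        assert mamdani_score(fis, {"x": -3.0}).crisp == mamdani_score(fis, {"x": 0.0}).crisp

    def _oracle(self, fis, inputs, n=400_001):
        """Independent brute-force Mamdani: np.interp memberships, dense grid."""
        strengths = {}
        for rule in fis.rules:
            ms = []
            for inp, lbl in zip(fis.inputs, rule.antecedents):
                a, b, c, d = inp.mfs[lbl].knots
                x = np.clip(inputs[inp.name], *inp.universe)
                xp = [a, b, c, d]
                fp = [0.0, 1.0, 1.0, 0.0]
                if b == a:
                    xp, fp = [a, c, d], [1.0, 1.0, 0.0]
                if d == c:
                    xp, fp = xp[:-1], fp[:-1]
                ms.append(float(np.interp(x, xp, fp, left=0.0, right=0.0)))
            s = min(ms)
            strengths[rule.consequent] = max(strengths.get(rule.consequent, 0.0), s)
        lo, hi = fis.output.universe
        y = np.linspace(lo, hi, n)
        agg = np.zeros_like(y)
        for lbl, s in strengths.items():
            e, f, g = fis.output.mfs[lbl].knots
            xp, fp = [e, f, g], [0.0, 1.0, 0.0]
            if f == e:
                xp, fp = [f, g], [1.0, 0.0]
            if g == f:
                xp, fp = [e, f], [0.0, 1.0]
            mf_y = np.interp(y, xp, fp, left=0.0, right=0.0)
            fired = s * mf_y if fis.implication == "prod" else np.minimum(s, mf_y)
            agg = agg + fired if fis.aggregation == "sum" else np.maximum(agg, fired)
        area = np.trapezoid(agg, y)
        if area <= 1e-12:
            return 0.5 * (lo + hi)
        return float(np.trapezoid(agg * y, y) / area)

    def test_engine_matches_brute_force_oracle_on_random_systems(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            k = int(rng.integers(1, 4))
            dirs = [("increasing", "decreasing")[rng.integers(0, 2)] for _ in range(k)]
            fis = default_fis([f"x{i}" for i in range(k)], dirs)
            if trial % 2:  # exercise the clipping variant too
                fis = dataclasses.replace(fis, implication="min", aggregation="max")
            inputs = {f"x{i}": float(rng.uniform(-0.2, 1.2)) for i in range(k)}
            res = mamdani_score(fis, inputs)
            assert res.crisp == pytest.approx(self._oracle(fis, inputs), abs=1e-6)

    def test_crisp_always_inside_extreme_label_centroids(self):
        rng = np.random.default_rng(3)
        fis = default_fis(["a", "b"], ["increasing", "decreasing"])
        for _ in range(50):
            x = {"a": float(rng.uniform(0, 1)), "b": float(rng.uniform(0, 1))}
            crisp = mamdani_score(fis, x).crisp
            # tolerance covers the 2001-point defuzzification grid error
            assert 1.0 / 3.0 - 1e-6 <= crisp <= 5.0 / 3.0 + 1e-6


class TestDiscretiseAndCombine:
    @pytest.mark.parametrize(
        "crisp,expected",
        [(5 / 3, 2), (0.5, 0), (1.0, 1), (1.5, 1), (0.49, 0), (0.51, 1), (2.0, 2), (0.0, 0)],
    )
    def test_discretise_nearest_with_half_points_down(self, crisp, expected):
        assert discretise(crisp) == expected

    def test_discretise_range_checked(self):
        with pytest.raises(ValidationError):
            discretise(2.1)

    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([1, 2, 1], 1),  # partial completion of a three-sub-motion item
            ([2, 2, 2], 2),  # full completion
            ([0, 2, 2], 0),  # any failed sub-motion fails the item
            ([1], 1),
            ([2, 1], 1),
            ([0], 0),
        ],
    )
    def test_combine_subscores(self, scores, expected):
        assert combine_subscores(scores) == expected

    def test_combine_rejects_bad_input(self):
        with pytest.raises(ValidationError):
            combine_subscores([])
        with pytest.raises(ValidationError):
            combine_subscores([1, 3])

    @settings(deadline=None)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=6))
    def test_combine_permutation_invariant_and_idempotent(self, scores):
        base = combine_subscores(scores)
        assert combine_subscores(list(reversed(scores))) == base
        assert combine_subscores(sorted(scores)) == base
        assert combine_subscores([base]) == base


class TestRuleBase:
    def test_k1_increasing_maps_labels_to_levels(self):
        rules = {r.antecedents[0]: r.consequent for r in default_rule_base(1, ["increasing"])}
        assert rules == {"low": "low", "medium": "medium", "high": "high"}

    def test_k1_decreasing_inverts(self):
        rules = {r.antecedents[0]: r.consequent for r in default_rule_base(1, ["decreasing"])}
        assert rules == {"low": "high", "medium": "medium", "high": "low"}

    def test_k3_weakest_link(self):
        rules = {
            r.antecedents: r.consequent
            for r in default_rule_base(3, ["increasing", "increasing", "decreasing"])
        }
        assert len(rules) == 27
        # all good (ROM high, MV high, SD low) -> high score
        assert rules[("high", "high", "low")] == "high"
        # any oriented input at its bad end caps the score at low
        for combo, out in rules.items():
            oriented = [
                {"low": 0, "medium": 1, "high": 2}[c] if i < 2
                else {"low": 2, "medium": 1, "high": 0}[c]
                for i, c in enumerate(combo)
            ]
            assert out == ("low", "medium", "high")[min(oriented)]

    def test_rule_base_completeness_enforced(self):
        fis = default_fis(["a", "b"])
        with pytest.raises(ValidationError):
            FisSpec(inputs=fis.inputs, rules=fis.rules[:-1])

    def test_monotone_crisp_output_under_grid_sweep(self):
        fis = default_fis(["a", "b", "c"], ["increasing", "increasing", "decreasing"])
        sweep = np.linspace(0, 1, 21)
        for base in itertools.product([0.1, 0.5, 0.9], repeat=2):
            for axis in range(3):
                crisps = []
                for v in sweep:
                    x = dict(zip("abc", np.insert(np.asarray(base), axis, v)))
                    crisps.append(mamdani_score(fis, x).crisp)
                diffs = np.diff(crisps)
                if axis == 2:  # decreasing input: crisp must not increase
                    assert np.all(diffs <= 1e-9)
                else:
                    assert np.all(diffs >= -1e-9)


class TestSerialisation:
    def test_fis_round_trips_through_dict(self):
        fis = default_fis(["rom_ratio", "mv_ratio", "sd_norm"],
                          ["increasing", "increasing", "decreasing"])
        clone = FisSpec.from_dict(fis.to_dict())
        assert clone == fis
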