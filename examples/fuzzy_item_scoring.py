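"""Score one angle item directly from its feature ratios.

Shows the fuzzy machinery in isolation: the three inputs of an angle item
(range-of-motion ratio, mean-velocity ratio, normalised side-to-side
deviation), their low/medium/high memberships, the crisp Mamdani output in
[0, 2] and the discretised item score.
"""

from fmaue.fuzzy import default_fis, discretise, mamdani_score, trapezoid_membership

fis = default_fis(
    ["rom_ratio", "mv_ratio", "sd_norm"],
    ["increasing", "increasing", "decreasing"],
)

scenarios = {
    "healthy-equivalent": {"rom_ratio": 1.0, "mv_ratio": 1.0, "sd_norm": 0.0},
    "partial completion": {"rom_ratio": 0.5, "mv_ratio": 0.55, "sd_norm": 0.3},
    "borderline":         {"rom_ratio": 0.7, "mv_ratio": 0.8, "sd_norm": 0.45},
    "failed":             {"rom_ratio": 0.05, "mv_ratio": 0.1, "sd_norm": 0.9},
}

for name, inputs in scenarios.items():
    res = mamdani_score(fis, inputs)
    memb = {
        inp.name: {l: round(trapezoid_membership(inputs[inp.name], inp.mfs[l]), 2)
                   for l in ("low", "medium", "high")}
        for inp in fis.inputs
    }
    print(f"{name}: inputs={inputs}")
    for k, v in memb.items():
        print(f"    {k:<10} memberships {v}")
    print(f"    crisp={res.crisp:.3f}  ->  score {discretise(res.crisp)}")
print()
print("The crisp value is the centroid of the fired output sets on [0, 2];")
print("1.667 / 1.0 / 0.333 are the pure high / medium / low centroids.")
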