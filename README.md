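# fmaue — automated Fugl–Meyer upper-extremity assessment

`fmaue` scores post-stroke upper-limb motor function on the Fugl–Meyer
Assessment, Upper Extremity (FMA-UE) scale from instrumented recordings
instead of a clinician's protractor: markerless skeleton tracking of the body
joints (Azure-Kinect-style vocabulary), 21 hand landmarks per hand
(MediaPipe numbering), and a 16×16 distributed thin-film pressure grid for
the five grasp tests. It automates the 30 items that need no reflex hammer,
scoring each 0/1/2 and classifying hemiplegia severity from the total. It is
aimed at rehabilitation-engineering groups building or validating automated
assessment rigs, and at anyone who needs a reference implementation of
ratio-based bilateral scoring with fuzzy inference.

## How scoring works

The affected limb is always judged against the patient's own healthy limb
performing the same motion, which removes inter-subject differences in
strength and range. For a joint-angle item with affected/healthy traces
θ_A(t), θ_H(t):

- ROM = max θ − min θ  (range of motion, degrees)
- MV = mean |dθ/dt|  (mean angular velocity, degrees/s)
- δ = √( Σᵢ Δdᵢ² / n ), the RMS pointwise deviation between the two sides
  after resampling both traces to a common length n

The fuzzy inputs are AROM/HROM, AMV/HMV and δ/HROM on the [0, 1] ratio
domain. Task items use analogous ratios: hand-to-hip length ratio
α = min d_AHC / d_OHC (item 12), finger–nose vertical ratio γ = Δd / d_FON
and shoulder-symmetry ratio β (item 32), fingertip mean/peak speed and mean
acceleration (items 31, 33), and thresholded grip-force sums
AFsum/HFsum over the pressure grid (items 26–30).

Each sub-motion is scored by a small Mamdani fuzzy inference system: three
trapezoidal membership functions per input (low [−0.4,−0.1,0.1,0.4], medium
[0.1,0.4,0.6,0.9], high [0.6,0.9,1.1,1.4]), three triangular output sets on
[0, 2] ([0,0,1], [0,1,2], [1,2,2]), min rule firing over a generated
monotone rule base, and centroid defuzzification. Multi-sub-motion items
combine their sub-scores S₁…S_k as

    R = 0 if any Sᵢ = 0;  2 if all Sᵢ = 2;  1 otherwise.

The total over 30 items (max 60) maps to severity: < 32 severe, 32–57
moderate, ≥ 58 mild.

## Worked example

No patient data ships with the package; the synthetic module generates
paired healthy/affected recordings with a known, controllable deficit:

```python
from fmaue import ImpairmentProfile, assess, gen_recording

profile = ImpairmentProfile(rom_scale=0.7, velocity_scale=0.7,
                            force_scale=0.6, tremor_amplitude=2.0, seed=42)
report = assess(gen_recording(profile))
print(report.total, report.severity)
```

prints `30 severe`: with range and speed at 70 % and grip force at 60 %,
every item's feature ratios land in the "medium" membership region and score
1 (the finger–nose tremor item scores 0 — tremor enters fingertip
acceleration quadratically in its frequency), for a total of 30/60, i.e.
severe hemiplegia. Driving the fuzzy system directly shows the scale ends:

```text
healthy-equivalent: rom_ratio=1.0 mv_ratio=1.0 sd_norm=0.0 -> crisp 1.667 -> 2
partial completion: rom_ratio=0.5 mv_ratio=0.55 sd_norm=0.3 -> crisp 1.000 -> 1
failed:             rom_ratio=0.05 mv_ratio=0.1 sd_norm=0.9 -> crisp 0.333 -> 0
```

The `examples/` directory has one short script per capability (end-to-end
scoring, the fuzzy engine in isolation, grip-force features, the
impairment dose-response curve); each prints what it computes and what the
numbers mean. A thin CLI wraps the same library:

```sh
fmaue simulate --impairment 0.5 --seed 3 --out rec.json
fmaue assess --recording rec.json --out report.json
fmaue registry          # dump the 30-item motion/feature table
```

## Layout

- `src/fmaue/datamodel.py`, `io.py` — domain types, JSON/CSV schemas
  (machine-readable schemas in `src/fmaue/schemas/`)
- `preprocess.py` — zero-phase Butterworth filtering (4th order, 12 Hz),
  resampling, hand-to-skeleton alignment
- `kinematics.py` — thorax/humerus coordinate systems, all angle traces
- `features.py` — ROM/MV/δ, reach, tremor and grip-force features
- `fuzzy.py` — membership functions, Mamdani engine, score combination
- `registry.py`, `scoring.py` — the 30-item table and the full pipeline
- `synthetic.py` — paired-recording generator with known impairment
- `cli.py` — `fmaue assess | simulate | registry`

`docs/methods.md` documents the model conventions, parameter choices and
known limitations in detail.
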