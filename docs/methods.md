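# Methods

This note documents how `fmaue` turns recorded joint trajectories and
force grids into item scores: the conventions chosen where the published
description leaves freedom, the parameters that matter, what the synthetic
generator does and does not emulate, and known limitations.

## Measurement model

**Canonical orientation.** All kinematics is written for a right arm. Clips
recorded on the left arm (identified by `*_L` arm joints without `*_R`
counterparts) are reflected across the sagittal plane (z → −z, left/right
joint names swapped) at load time. A reflected left hand is geometrically a
right hand, so one set of sign conventions serves both sides. Force-grid
sums are mirror-invariant; `mirror_force` exists for audit overlays only.

**Signal conditioning.** Every coordinate channel is filtered with a
fourth-order Butterworth low-pass at 12 Hz before any angle is computed.
The filter runs forward–backward (zero phase): scoring compares the two
sides point by point through the deviation δ, and a one-pass filter's group
delay would enter δ as a spurious lag. Filtering positions (rather than
derived angles) keeps the nonlinear angle maps from folding noise
asymmetrically. The 12 Hz band deliberately passes physiological tremor
(4–8 Hz), which items 31–33 must see. Sampling rate is carried explicitly in
the recording schema (`fs` > 24 Hz required); nothing assumes 30 Hz.

**Thorax frame.** Y_T runs from spine-chest to neck; the anterior axis X_T
is the ventrally-oriented normal of the plane spanned by Y_T and the
inter-shoulder line; Z_T = X_T × Y_T points right-lateral. For angles that
need an anterior reference while the shoulder girdle itself moves
(retraction, humerus axial rotation), the anterior axis is rebuilt from the
*hip* line when hips are tracked: the shoulder line follows the retracting
shoulder and would absorb roughly half the measured angle.

**Shoulder angles.** The humerus direction expressed in the thorax frame
yields an elevation angle and a plane of elevation (0° frontal, 90°
sagittal); the clinical traces are the projections
abduction = elevation·cos(plane) and flexion = elevation·sin(plane), both
computed with atan2 forms that stay well-conditioned near zero elevation.
Axial (internal/external) rotation is the rotation of the forearm's
component perpendicular to the humerus, measured against the projected
anterior axis; it is observable only with a flexed elbow, and undefined
samples (straight arm) carry the last defined value. A full Y-X-Y Euler
decomposition of the thorax→humerus rotation (`shoulder_angles`) is
provided and tested separately; the trace pipeline uses the projection
construction because the humerus frame's anterior axis is under-determined
from skeleton joints alone when the arm is straight.

**Elbow, wrist, forearm, fingers.**
Elbow flexion is 180° minus the interior upper-arm/forearm angle, so full
extension reads 0°. Wrist flexion is the signed angle between the forearm
axis and the hand axis (wrist → middle-finger base), dorsiflexion positive,
with the sign reference taken from the palm normal (landmarks 0, 5, 17).
Forearm pronation/supination is the rotation of the palm normal about the
forearm axis *relative to the clip's first sample*: the tests track change
during a motion, and an absolute anatomical zero is not observable from
landmarks. The transported reference (initial normal projected onto the
current plane ⊥ forearm) makes the measure exact under pure elbow motion.
Finger bend angles follow the published landmark-vector pairs (thumb: 3→4
vs 0→2; index 0→6 vs 7→8; middle 0→9 vs 10→12; ring 0→13 vs 14→16; little
0→17 vs 18→20) via the 3-D arccos form, which restricted to a plane equals
the printed 2-D expression exactly.

All traces are functions of relative geometry (including the "vertical"
direction of the finger–nose features, which is the thorax Y axis rather
than the camera Y), so a rigid rotation + translation of every joint leaves
every feature unchanged — a tested invariant (≤ 1e-6°).

## Features and their fuzzy encoding

For angle items: rom_ratio = AROM/HROM, mv_ratio = AMV/HMV, and
sd_norm = δ/HROM with δ the RMS pointwise deviation after resampling both
traces to n = 200 points (n is a sample count; results are insensitive to
it once both traces are on a common parameterisation). Healthy ROM is the
natural per-subject scale for δ, which is otherwise in degrees. All fuzzy
inputs are clipped to the [0, 1] ratio domain; the membership knots extend
beyond it (−0.4 … 1.4) so both edges sit on full low/high plateaus and an
affected side that outperforms the healthy side saturates at "high".

Ratio direction is resolved per feature so that *equal sides always score
2* and each published monotone statement holds:

- sd_norm, and the deviation-style inputs |AMA/HMA − 1| (item 31) and
  |Aβ/Hβ − 1| (item 32), are "decreasing" inputs: 0 is the good end, and
  the rule base inverts their labels (low ↦ level 2).
- The reach ratios α (item 12) and γ (item 32) shrink toward 0 as the
  target is reached, so "greater ratio of raw α" would mean worse — yet
  their printed definitions give 1 for no movement. Both are converted to
  completion fractions c = 1 − min ratio before ratio-ing affected over
  healthy; the resulting Ac/Hc is an ordinary increasing input that equals
  1 for equal sides and preserves the stated monotonicity.
- β compares the fingertip's horizontal distances to the two shoulders at
  the moment of closest nose approach; the deviation-from-1 form is used
  because lateral dysmetria can push the raw ratio either above or below 1.
- Grip items use AFsum/HFsum, the sums of per-cell maxima over the grasp,
  with cells below an effective-grip threshold zeroed (default 0.1 N, the
  sensor's detection floor; configurable).

## The fuzzy engine

Membership functions are the published parameter vectors (see README); they
form a partition of unity on the input domain. Rule bases are generated:
each input label maps to an oriented level 0/1/2 and the consequent is the
*minimum* level — the weakest link caps the score, the conservative
clinical reading of the published monotone descriptions. The complete 3^k
base is validated (every combination exactly once).

Inference is Mamdani with min rule firing and centroid defuzzification on a
2001-point uniform grid over [0, 2] (grid error ≤ 5e-7 against a dense
reference). Two implication/aggregation variants are supported. The
default is the additive variant — product (scaling) implication with sum
aggregation — because scaling preserves each output set's centroid, making
the crisp score a weighted mean of the label centroids (1/3, 1, 5/3) and
hence exactly monotone in every oriented input. The clipping variant
(min/max) is available per config; it scores identically on the membership
plateaus but exhibits ~0.06 non-monotone centroid ripples where input
labels cross, an inherent artefact of clipped-set centroids that would
break the engine's monotonicity guarantee.

Crisp scores are discretised to the nearest integer with exact half-points
(0.5, 1.5) rounding down — the conservative choice. Multi-sub-motion items
combine sub-scores with the published any-0 → 0 / all-2 → 2 / else 1 rule.
Items 31–33 share one finger–nose clip whose features are computed once and
routed to three item specs. Items 24/25 run two sub-systems (thumb and
four-finger mean) on bend-angle excursion and velocity ratios; for mass
extension the excursion is measured from the initial (flexed) posture, so
the same max |θ(t) − θ(0)| recipe serves both directions.

**Severity.** The published bands (< 32 severe, 32–57 moderate, ≥ 58 mild)
refer to the 66-point clinical scale; the automated total spans 30 × 2 = 60
points. By default the bands are applied to the raw total — reported with
that caveat — and an optional rescale by 66/60 can be enabled
(`rescale_total=True`). Items that cannot be scored (missing clips, a
degenerate healthy reference) are excluded from the total and listed in the
report's diagnostics, never silently scored 0.

## Synthetic data: what it emulates and what it does not

The generator exists so that every stage — and the end-to-end score — can be
tested against ground truth without hardware or patients. Healthy motion is
a minimum-jerk there-and-back angle profile (smooth, zero endpoint
velocity) on a fixed posed skeleton; per-motion baselines and amplitudes
are chosen as plausible test excursions (e.g. abduction 0–95°, elbow
excursion 60°, wrist 30°, finger bend 80°). Composite synergy clips (M1 six
phases, M2 three) run their degrees of freedom sequentially, each phase 5 s
at 30 Hz, with the elbow held slightly flexed so axial rotation stays
observable. The hand is posed with the same twist-transport convention the
kinematics measures, so commanded angles are recovered exactly in the
noise-free limit — a deliberate alignment that makes generator ground truth
meaningful, not a claim that real hands move this way.

The affected side re-executes the profile with range scaled by `rom_scale`
and total excursion rate by `velocity_scale` (realised as k =
velocity/rom cycles of the scaled wave; exact when k is a whole or half
cycle, approximate otherwise, and composite clips round k to whole cycles
to keep phases continuous). Tremor is a 5 Hz sinusoid on the moving degree
of freedom (amplitude in degrees; mapped to an equivalent lateral
displacement for the finger–nose path). Position noise is Gaussian,
default 0.1 mm SD on body joints and a fifth of that on hand landmarks —
the residual jitter after zero-phase smoothing. The default is set so that
recovered feature ratios are dominated by the commanded deficit (max−min
ROM estimation picks up extreme-value noise bias over long clips; at 0.5 mm
jitter that bias reaches several degrees); raising `noise_sd` is the dial
for robustness studies. Force grids are Gaussian finger-contact blobs at
plausible cell positions with healthy peak amplitudes around 12/7.6/6.3/
4.1/3.6 N (thumb → little) plus a palm patch, a 0.3 N sensor floor, an
envelope ramp over frames, and ~1 % multiplicative sensor noise (disabled
when the profile is noise-free).

Consequences for interpretation: passing the recovery suite shows the
*pipeline* is unbiased and monotone under controlled deficits; it says
nothing about pathological synergy coupling, occlusion artefacts, variable
timing, compensatory trunk motion, or marker-tracking failure modes, none
of which the generator emulates. The published clinical agreement figures
(Bland–Altman, Pearson r on real patients) are not reproducible without
patient recordings and are out of scope here.

## Numerical choices and degenerate inputs

- Zero-length segment vectors raise `GeometryError`; non-finite
  coordinates or forces are rejected at parse time.
- A healthy-side denominator of 0 (HROM, HMV, grip sum, completion)
  raises an "uninformative healthy reference" error naming the feature;
  the item becomes unscorable rather than producing an infinite ratio.
- The deviation resampling uses linear interpolation on a uniform [0, 1]
  parameterisation, endpoints preserved.
- Hand-to-skeleton alignment is translation + uniform scale only; a
  rotation cannot be determined from the two available correspondences
  (wrist, middle fingertip) and the two sensors share the camera frame.
- Gimbal proximity in the Euler decomposition (elevation within ~1e-6 of
  0°/180°) deterministically assigns the full Y rotation to the first
  angle.
- Unscorable items never enter the total; determinism is absolute (same
  recording bytes → same report bytes; the generator is seeded).

## Known limitations

- Severity bands on a 60-point total are a conservative reinterpretation
  of the 66-point clinical bands (see above).
- `velocity_scale` below half of `rom_scale` cannot be realised: the mean
  velocity of a motion that must still cover the commanded range has a
  floor of one half-cycle per clip.
- The wrist-stability items (19/21) treat the 15° dorsiflexion target as a
  measured excursion fed to the fuzzy system, not as a hard pass/fail gate;
  the published description does not say which is intended.
- Sub-motion segmentation is assumed done upstream: recordings supply one
  clip per motion code, and no automatic segmentation is attempted.
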