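# Methods

## Problem and scope

`spinekin` derives three-dimensional thoracic, lumbar and hip segment angles
from two simultaneous measurement systems — wearable IMUs reporting fused
orientation quaternions at 62.5 Hz, and an optical motion-capture (OMC)
system tracking rigid three-marker clusters at 120 Hz — and quantifies how
well the wearable system agrees with the optical gold standard across six
clinical range-of-motion tasks (flexion, extension, left/right axial
rotation, left/right side bend), five repetitions each, two trials per
participant. Because no public dataset of this design exists, the package
ships a synthetic cohort generator that renders the same ground-truth
trunk motion through both measurement channels, so every stage is verified
by parameter recovery against known truth.

## Coordinate conventions

The global frame is Z-up with gravity (0, 0, −9.81) m/s². Body frames are
right-handed with X anterior, Y medial–lateral pointing left, Z vertical.
Plane angles: sagittal = rotation about +Y (positive = forward flexion),
transverse = rotation about +Z (positive = left rotation), frontal =
rotation about −X (positive = left side bend; the left-positive frontal
sign is a package convention chosen for symmetry with the transverse
convention). Euler sequences are intrinsic, one per movement family:

| movement | order (primary–secondary–tertiary) |
|---|---|
| flexion / extension | sagittal – frontal – transverse (`FE_SB_AR`) |
| side bend | frontal – sagittal – transverse (`SB_FE_AR`) |
| axial rotation | transverse – sagittal – frontal (`AR_FE_SB`) |

Intrinsic composition was chosen because joint-coordinate conventions in
biomechanics are intrinsic; the choice is centralized in `rotations.py` so
one mapping flips it. All angles crossing module boundaries are degrees.

## Functional body calibration

Each sensor's arbitrary mounting frame is converted to a body frame from
two measured directions: the medial–lateral axis is the principal rotation
axis of one flexion repetition — the dominant eigenvector of the summed
outer products of the rotation vectors of R₀⁻¹R_t, signed so flexion is
positive — and the vertical axis is the gravity direction during quiet
standing (IMU: transposed orientation applied to global up; OMC: the same
from the cluster orientation). The anterior–posterior axis is their cross
product; a second cross product re-derives the vertical so the frame is
exactly orthonormal, with the medial–lateral axis kept exact. The principal-
axis fit was chosen over angular-velocity averaging because it needs no
gyroscope signal and is therefore identical for both systems.

The static-pose detector accepts a window when the chordal means of its
four quarters agree within 2° **and** no frame deviates more than 3 × 2°
from the window mean. Raw per-frame excursion alone misclassifies
stationary sensor jitter as movement; the two-part test separates trend
(posture drift, ramps) from transients (spikes) while tolerating zero-mean
noise. Defaults: 0.5 s window, 2° threshold, 15° minimum calibration
excursion, 10° minimum axis separation — all configurable.

## Segment kinematics

For a sensor pair (S1 = distal, S2 = proximal) the body-to-body rotation is
the four-factor product

```
R_S1body→S2body = R_S2local→S2body · R_global→S2local · R_S1local→global · R_S1body→S1local
```

computed identically for both systems. Pairings: thoracic = T1/T2 vs
T12/L1, lumbar = T12/L1 vs L5/S1, hip = femur vs L5/S1 (the hip reference
and the distal-as-S1 order are package decisions, exposed in the config).
The rotation path is low-pass filtered on the rotation manifold (zero-phase
4th-order Butterworth on the rotation-vector components, default cutoff
3 Hz ≈ 10 × the 0.33 Hz repetition fundamental; signals are padded with
their local edge means so the trailing static frames are not biased by a
single noisy boundary sample). Every trial is then normalized to the
participant's static posture: the chordal mean (projection of the
elementwise mean onto SO(3)) of the last five frames, inverted and
right-multiplied into every frame. Euler angles follow under the movement's
order.

## Repetition segmentation and peak extraction

The visual repetition identification of a human rater is replaced by peak
detection on the whole-trunk (T1-vs-L5) reference trace: 2 Hz zero-phase
low-pass, minimum prominence 5°, minimum separation 1.5 s, boundaries at
between-peak minima. Four detected repetitions against five expected is a
warning (such trials occur in practice); fewer is a failure. When a
segment's own excursion is badly truncated by the reference windows (any
window capturing < 60 % of the segment's whole-trial peak — the segment led
or lagged the trunk), that segment is re-segmented on its own trace.

Per repetition, the signed primary-plane peak is taken in the *effective*
direction: the direction with the larger absolute excursion in the window
wins (countermovement), ties go to the cued direction. The summary value is
the mean of peak magnitudes across repetitions (magnitudes in the effective
direction; the direction itself is recorded via the signed peaks).
Non-primary (coupled) motion is a whole-trial envelope, max − min per
plane, not a per-repetition quantity. Segment movements with fewer than
four usable repetitions are excluded with a logged reason.

## Agreement statistics

Paired per-participant tables (trial 1 vs trial 2 of the IMU system for
reliability; IMU vs OMC on trial-1 values for validity) are compared with:

* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measurement — from the ANOVA decomposition, with the exact F-based 95 %
  interval; `ICC3_1` and `ICC2_k` are available behind a config enum.
  Bands: poor < 0.5, moderate 0.50–0.75, good 0.75–0.90, excellent > 0.90
  (upper endpoints assigned downward). Negative ICCs and CI bounds are
  reported as computed.
* **RMSE** over participants of the per-participant difference.
* **Bland–Altman** bias: mean and sample SD (ddof = 1) of IMU − OMC
  differences; plots show ±2 SD about the line of equality. Outliers are
  differences more than 2 sample SDs from the *mean* bias (strict
  inequality, single pass), and the **adjusted RMSE** is recomputed on the
  outlier-free subset.

Validity uses trial-1 values so that a first-trial data loss (e.g. marker
occlusion) removes the participant from the affected rows — reproducing
per-row N annotations — while a second-trial loss only affects
reliability. Report tables: reliability 18 segment movements × 3 planes;
primary validity 18 rows (ICC + CI + band, RMSE, adjusted RMSE); bias
6 movements × 3 segments; non-primary validity 18 rows × 2 planes.
Bland–Altman plots are produced for the primary plane only.

## Synthetic cohort

Ground truth is a kinematic chain from a pelvis-level base: raised-cosine
repetition profiles (smooth, zero end velocity) in the primary plane whose
peaks equal the commanded amplitudes exactly, full-period sinusoids in the
coupled planes (whole-trial excursion exactly twice the coupled amplitude),
rest gaps between repetitions, a calibration recording at trial start
(stomp acceleration spike ≥ 4 g, one 25° flexion repetition moving every
sensor, static tail) and a ≥ 5-frame static tail ending every recording.
Default amplitudes are typical healthy-adult values (e.g. lumbar flexion
50°, thoracic axial rotation 35°, hip flexion 60°) with ±15 % multiplicative
between-subject spread, ±2° between-trial jitter, and an occasional lumbar
countermovement during axial rotation.

The noise model and its defaults (the cohort's standard conditions):

| parameter | default | emulates |
|---|---|---|
| IMU orientation noise | 0.7° total angular RMS, band-limited 5 Hz | fusion output jitter |
| IMU drift | 1°/min about a random axis | heading drift |
| mounting misalignment | 5° SD per sensor per trial | skin placement |
| marker noise | 0.2 mm | optical reconstruction |
| soft-tissue artifact | 1 mm at 0.8 Hz, common-mode + 20 % per-marker | skin/clothing moving the casing |
| inter-trial amplitude SD | 2° | biological variability |
| inter-system scatter | 3° SD per participant | calibration/fusion idiosyncrasy |

The inter-system channel adds b + N(0, s²) per participant to the IMU's
primary amplitudes — the mechanism behind the bias-recovery study. An
optional "outlier participant" multiplies that error by 8 (non-physiological
IMU values with intact calibration, as the real outliers present); optional
injections also provide a battery-depleted second trial and a fully
occluded T12/L1 cluster in one trial-1 recording.

What the simulator does **not** model: magnetometer disturbance,
physiologically detailed multi-joint coupling, translation of segments,
marker swaps, and real soft-tissue dynamics. Passing recovery tests
therefore demonstrates the correctness of the processing chain under the
stated error model, not the field accuracy of any particular sensor.

## Problem sizes used by the tests and acceptance script

Noise-free end-to-end recovery uses the full study design (16 participants
× 2 trials × 6 movements × both systems; tolerance 0.1°). The default-noise
Monte-Carlo check uses 100 seeded 3-participant single-movement runs, with
error bounds propagated from the noise model (filter retention, peak
extreme-value inflation, drift). The bias-recovery study uses 200
replicates split over b ∈ {−5°, 0°, +5°}, each an 8-participant single-trial
flexion cohort with shortened (2 s) repetitions and known scatter s = 2°;
coverage is assessed against ±2 s/√n (the known-s z interval — the stated
≥ 95 % coverage is a property of the known-sigma interval, not the sample-SD
t interval). These sizes keep each study's runtime proportionate while
leaving the estimators' distributions unchanged.

## Known limitations

* The marker dialects (TRC and a wide CSV) are package-defined stand-ins:
  the vendor IMU app's file format is unpublished, and C3D is out of scope;
  a column-mapping block in the config adapts foreign CSVs.
* Euler decomposition near the ±90° secondary-angle singularity is flagged
  and resolved deterministically (tertiary = 0); trunk motion does not
  approach it.
* Drift is not corrected between repetitions (deliberately, matching the
  measured protocol); the drift term therefore appears in the IMU error
  budget.
* ICC interpretation degrades when between-subject variance is small; the
  implementation warns and reports the degenerate value rather than masking
  it.
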