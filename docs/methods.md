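# Methods

## Scope and model

`jointangles` models one validation experiment: a subject stands facing a
depth camera and performs repetitions of shoulder abduction (left, SAL, or
right, SAR) while being recorded simultaneously by a marker-based optical
motion-capture reference and a marker-less skeleton tracker.  The package
simulates the experiment, computes three joint angles from both streams,
quantifies their agreement, and fits per-subject calibration regressions.

### Coordinate frame and skeleton

Camera-centered coordinates: x lateral (subject's left positive), y
vertical up with the camera origin 1 m above the ground, z depth toward
the subject.  The subject stands on the camera axis at 2.0, 2.5 or 3.5 m.
Ten keypoints are tracked: ears, C7, chest (suprasternal), shoulders,
elbows, wrists.

Segment lengths are fixed fractions of standing height *h*: upper arm
0.186 h, forearm 0.146 h, shoulder half-width 0.129 h, shoulder height
0.82 h, ear height 0.93 h.  The chest marker is placed at shoulder height
and in the shoulders' frontal plane.  This placement is deliberate: the
virtual shoulder joint copies the chest marker's height and depth, and
putting the suprasternal marker at clavicle level makes the virtual
shoulder coincide with the physical shoulder on noiseless data, so a
hanging arm reads α = 0° and a horizontal arm α = 90° exactly.  A chest
marker placed lower (e.g. mid-sternum) would bias α of a horizontal arm
tens of degrees above 90° and break those anchors; on real bodies the
suprasternal notch is within a few centimetres of clavicle height, so the
idealisation is mild.

### Exercise kinematics

Each repetition sweeps the abduction angle 0 → peak → 0 with a
raised-cosine profile φ(τ) = peak · (1 − cos 2πτ/T)/2 over T seconds,
followed by a rest; the default is 5 repetitions to a 90° peak.  T is a
per-subject constant (3.2–4.8 s, derived deterministically from the
subject id) — subjects differ in sweep speed, which is the only
inter-subject kinematic difference modelled.  The elbow stays fully
extended (shoulder–elbow–wrist collinear) and motion is confined to the
frontal plane, so ground-truth β ≡ 180° and γ ≡ 90°.  The contralateral
arm hangs at 0°.

### Observation models

**Reference (mocap-like), 256 fps.**  Each marker is the true joint plus a
rigid anatomical offset expressed in the local upper-arm frame
(longitudinal, posterior, lateral), plus i.i.d. Gaussian noise (default sd
1 mm, distance-independent).  The default elbow offset is 30 mm posterior
— the marker is glued on the back of the elbow — which shifts β of an
extended arm to 180° − atan(d/ua) − atan(d/fa), about 167–168° for adult
segment lengths: a constant, geometry-explainable bias of the class seen
in marker-based recordings.

**Tracker (sdk-like), 30 fps.**  Per-joint i.i.d. Gaussian noise with sd
σ(D) = σ₂ₘ · (D/2 m)^p, defaults σ₂ₘ = 8 mm and p = 1.5.  These are free
parameters of the synthetic world chosen to make the distance trend
clearly visible at realistic error magnitudes (2–4° α MAE); no acceptance
value depends on their exact setting, only on the induced ordering.
Frames where the exercising arm's angular speed exceeds 45 °/s lose the
elbow and wrist keypoints with probability 0.3 per frame (fast motion
blurs the depth stream); only elbow and wrist drop because proximal
joints move little during abduction.  The raised-cosine peak speed is
peak·π/T ≈ 60–90 °/s, so dropouts concentrate at mid-sweep.

All randomness flows from `numpy.random.default_rng` seeded per trial;
identical configurations give byte-identical outputs.

## Angle engine

All three angles are arccos of a clamped normalized dot product (the
argument is clipped to [−1, 1] to absorb rounding), in degrees in
[0, 180].

* α: angle between (virtual shoulder → elbow) and world −y.  The elbow,
  not the wrist, is the arm-vector endpoint (equivalent while β ≈ 180°;
  the wrist is selectable).  World −y stands in for a trunk axis because
  the marker set has no pelvis landmarks; subjects are assumed upright.
* β: angle at the elbow between the physical shoulder and the wrist — the
  elbow angle needs the true segment, the virtual joint exists only to
  harmonise α between systems.
* γ: angle between the arm vector and the anterior-pointing frontal-plane
  normal, estimated per frame as cross(down, right shoulder − left
  shoulder) and falling back to the toward-camera depth axis when a
  shoulder is invalid.  The anterior orientation makes "arm pointing at
  the camera" read 0°; an in-plane arm reads 90° under either sign.

**Gap filling (LOCF).**  Invalid required joints take their most recent
valid position; frames before a joint's first detection are dropped; a
joint that never appears makes the trial unrecoverable.  Filled frames
are flagged and the flag propagates to every downstream sample, which is
what lets the calibration analysis separate dropout-corrupted frames from
clean ones.

## Alignment

Both angle series are linearly interpolated onto a uniform 30 fps grid
(the slower stream's rate; downsampling the reference avoids inventing
detail) spanning their own time range — no extrapolation, no smoothing
(the analysis deliberately sees raw fluctuations).  The residual timing
offset is the integer-frame lag maximising the normalized
cross-correlation (per-window mean-removed and unit-scaled, so overlap
length carries no advantage) of the α traces over ±2 s; ties break toward
the smallest |lag|.  The same lag is applied to β and γ; alignment only
slices and trims, never alters values.  An overlap shorter than one
repetition is an error.

## Agreement statistics

Per aligned pair: MAE, RMSE, R², Spearman, and mean/sd of differences
(the difference plot uses x = mean of the two methods, lines at mean and
mean ± sd).  R² defaults to the squared Pearson correlation between test
and reference: this reading coexists with a large constant bias and is
the convention under which R² near 1 accompanies α MAE of several
degrees; the 1 − SSres/SStot-about-identity variant is available as
`r2_variant="identity"`.  All standard deviations are population sds
(divide by N), matching the convention of the packaged demographic table.

The distance effect is tested with a Friedman test whose matched unit is
the per-subject-per-exercise trial MAE (one value per unit per distance),
not per-frame samples — frames are autocorrelated and frame counts differ
across distances; post-hoc pairwise Wilcoxon signed-rank tests are
Bonferroni-corrected over the three pairs.  Degenerate inputs follow
explicit conventions: identical Friedman columns report statistic 0 and
p = 1; all-zero Wilcoxon differences report p = 1; a constant sample
fails normality tests with p = 0 rather than crashing; Shapiro–Wilk input
is thinned evenly above n = 5000 where the test is unreliable.

## Personalized calibration

Strata are single subject × exercise × distance datasets of frame-level
(tracker α, reference α) pairs; a distance feature would be redundant
within a stratum.  Each stratum is shuffled and split 80/20 once (seeded
by CRC32 of the stratum key mixed with the global seed, kept below 2³¹)
and all ten families fit the identical split; test error is always
accompanied by the uncalibrated identity-mapping baseline on the same
test indices.  Default hyperparameters: ridge α = 1.0, lasso α = 0.01,
elastic net α = 0.01 / l1 = 0.5 (all on standardized inputs, which keeps
the four linear families within 0.1° of each other on well-conditioned
data), polynomial degree 3, decision-tree depth 6, random forest 200
trees (depth 8), gradient boosting 200 stages at learning rate 0.1, SVR
C = 10 with scale-based RBF gamma.  Strata under 10 samples or with a
constant input are recorded as failed and skipped.  Evaluation uses the
held-out 20% only.

Information destroyed by LOCF is not recoverable by calibration: on
dropout-affected frames the tracker reports a stale angle whose error is
not a function of the reported value, so any univariate mapping leaves
their residuals above clean-frame residuals.  The test suite asserts this
irreversibility directly.

## What the simulator does and does not emulate

It emulates: paired 256/30 fps streams, anatomically offset markers,
distance-dependent keypoint noise, velocity-gated elbow/wrist dropouts,
per-subject movement speed, and the published 14-subject demographic
roster (packaged verbatim for offline demographic checks).

It does not emulate: skeletal-model biases of real pose-estimation SDKs
(systematic, posture-dependent joint mislocalisation), soft-tissue and
marker-wobble artefacts, out-of-plane compensation movements, occlusion,
lighting effects, or inter-repetition variability of peak range.  Passing
tests therefore demonstrate the correctness and statistical behaviour of
the *analysis machinery* under a controlled generative model — not the
field accuracy of any particular sensor.  Headline agreement numbers from
real recordings (α MAE near 9–10° at 2 m) are not reproduction targets
here; the synthetic defaults produce smaller, trend-preserving errors.

## Problem sizes and numerical choices

Cohort analyses in the tests use 14 subjects × 3 distances × 5
repetitions (≈ 20–25 s per trial, ~6 400 truth frames at 256 fps); the
distance-trend check replicates this over 20 seeds.  Statistical-battery
calibration uses 1 000 null simulations with 20 matched units.  The
acceptance script's anchors use a full 5-repetition noiseless trial.
Angle computation is vectorised; the per-pose functions define the
semantics and the array path is tested against them.

Known limitations: the body-down reference for α assumes an upright
trunk; the frontal-plane normal degrades to the camera axis if a shoulder
is lost; LOCF creates plateau artefacts by design; linear interpolation
slightly low-passes the reference when downsampling (bounded by the
standard second-derivative interpolation error bound, asserted in tests).
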