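# Methods

This note documents the models, conventions, and numerical choices behind
`balancekit`, and what the synthetic cohorts do and do not establish about
real data.

## Study design emulated by the generator

A cohort of 23 participants with chronic ankle instability (CAI) and 23
healthy controls (HC) performs single-leg stance, three 15-s trials per
condition, on a static platform and on one translating mediolaterally as
a sinusoid at 1.6 Hz with 20 mm peak-to-peak displacement. Markers are
sampled at 100 Hz, force plates at 1 kHz. Trials are trimmed to their
middle 10 s — anchored, on moving trials, at the platform zero crossing
where it starts moving medially — giving 1,000 analysed time points per
channel; with 4 joints x 3 planes that is the 12,000-variable waveform
space used by the PCA. A note on the platform: with a 10 mm amplitude at
1.6 Hz the peak acceleration A(2πf)² is ≈ 1.01 m/s²; the generator
follows the stated frequency and amplitude and applies no acceleration
clamp.

## Signal conditioning

All channels are filtered with a fourth-order 10 Hz low-pass Butterworth,
applied forward-backward (zero phase, standard in gait analysis) so
kinematic and kinetic channels stay time-aligned; no cutoff correction is
applied for the dual pass, which doubles the effective order. Force data
are downsampled 1 kHz → 100 Hz by cubic-spline interpolation on the
aligned time grid (exact for polynomials up to degree 3). Windows are
0-based half-open sample ranges; 10 s at 100 Hz is exactly 1,000 samples.
Static trials take the centred window (no event is defined for them).
Marker gaps of at most 10 consecutive frames are spline-filled before
filtering; longer gaps are a hard error rather than silently interpolated.

"Medially moving" is resolved through the stance side: medial is toward
the body midline of the support foot (−X lab for a right stance, +X for a
left stance, with +X the subject's right). When several qualifying zero
crossings leave a full window, the one nearest the centred start is used,
ties resolved to the earlier crossing.

## Kinematics

Segment orientations are estimated per frame by a least-squares rigid-body
(orthogonal Procrustes) fit of each marker cluster to its calibration
template. This keeps frames exactly orthonormal under marker noise and is
robust compared with direct anatomical-axis construction; with 0.5 mm
marker noise and the default 4-marker shank/thigh clusters the frame error
is ≈ 0.3° RMS. Clusters with fewer than three markers or collinear
geometry are rejected.

Joint angles are the Cardan X-Y-Z decomposition of the relative rotation
of the segment further from the support foot with respect to the nearer
one (ankle: foot→shank, knee: shank→thigh, hip: thigh→pelvis, torso:
pelvis→torso). Axes: X mediolateral (sagittal-plane angle,
dorsiflexion/flexion positive), Y anteroposterior (frontal plane,
inversion/adduction positive), Z longitudinal (horizontal plane, internal
rotation positive). Left-stance data are reflected about the sagittal
plane and processed against the right-side template, which mirrors all
conventions consistently. Angles are unwrapped per channel (360° period)
before differentiation; samples with |frontal angle| > 85° are flagged as
gimbal-proximal. Angular velocity is the first time-derivative via central
differences (one-sided at the ends, exact on linear ramps); an `order=2`
switch yields the second derivative for sensitivity analyses, but the
first derivative is the defensible reading of an angular *velocity* and is
the default everywhere. Range of motion is max − min per channel; RMS
angular velocity is the root mean square over the trimmed window.

## Posturography

COP follows the plate moment balance
`COP_x = (−M_y − F_x d_z)/F_z + o_x`, `COP_y = (M_x − F_y d_z)/F_z + o_y`
with a 20 N load threshold below which samples are rejected as unloaded.
The foot rectangle is built from the trial-averaged first and fifth
metatarsal, distal phalanx, and calcaneus markers: the long axis runs
calcaneus → phalanx in the horizontal plane, and the rectangle is the
bounding box of the four projections in the (long, mediolateral) foot
frame. On moving trials both markers and COP are expressed in the
platform frame (the plate rides the platform and the boundary is
anatomical), so TTB measures COP motion relative to the foot.

TTB-ML uses the central-difference velocity of the filtered, downsampled
(100 Hz) COP: moving laterally the relevant boundary is the lateral edge,
medially the medial edge. Samples with |v| < 1e−6 m/s take the cap value
(the 10-s trial duration) and are excluded from minima; positions outside
the rectangle clip to 0 and are likewise flagged. Local minima are valid
samples strictly lower than their nearest differing neighbours inside a
contiguous valid run, plateaus counted once at their first sample — a
deterministic definition that a plain-loop oracle can check exactly. A
trial whose series is monotone within every valid run has no interior
minimum; the global minimum then stands in as the single minimum and the
summary is flagged degenerate rather than silently altered. SD of minima
uses the n−1 sample SD (0 for a single minimum). SDAmp is the sample SD
of COP distance from the trajectory centroid; sway velocity is path
length over elapsed duration.

A useful exact property: scaling the COP velocity by k while keeping the
path divides every valid TTB sample, and hence all three minima
summaries, by k. This is the mechanism by which the generator plants
group-by-condition TTB structure.

## Waveform PCA

Each participant contributes the pointwise mean of their three trials.
Standardization `Z_t = (X_t − μ_t)/s_t` is **column-wise across
participants** — the only coherent reading, since a per-variable SD is
undefined for one scalar per participant — with the n−1 sample SD;
columns with SD below 1e−12 are dropped and logged. Columns are laid out
channel-major (ankle-sagittal first, torso-horizontal last), each channel
contributing its 1,000 time points contiguously.

Components come from the SVD of the participant-centred matrix; the
retained count is the smallest k whose cumulative explained variance
reaches 90%. Component signs are oriented so the HC group-mean score is
non-negative (matching the convention of reporting CAI scores as
negative); sign flips change no reconstruction or p value, which is
asserted by test. Group comparison uses pooled-variance t-tests on each
retained component's scores with pooled-SD Cohen's d; no multiple-testing
correction is applied, but every report carries the family size. Welch
tests are available by flag.

Group-mean waveforms are reconstructed as
`X̂ = μ + s · (mean scores · selected loadings)`, restoring original
units; the full basis reproduces each participant's averaged waveforms to
numerical precision.

Leave-one-out surrogate validation refits the standardization and PCA n
times on n−1 participants. Because component order and sign are unstable
across refits, each surrogate is matched to the target component by
maximal absolute loading correlation with sign alignment; two candidates
within 0.01 in |r| are flagged ambiguous and both reported. Surrogates are
classified significant (p < .05), marginal (.05 ≤ p < .10), or
non-significant.

## Inference

The 2x2 mixed ANOVA (between: group; within: condition) reports F, df,
p, and partial eta squared `SS_effect/(SS_effect + SS_error)` with each
effect's own error term; an independent from-scratch sums-of-squares
decomposition is kept alongside as an oracle and agrees to 1e−9. Post
hocs are Bonferroni-adjusted with m = 2 per family — group within each
condition (independent t) and condition within each group (paired t) —
with 95% CIs of the mean differences. Shapiro–Wilk is offered as a
diagnostic only and never gates computation.

Stepwise regression is forward selection (enter the candidate with the
smallest partial-F p if p < .05) with backward pruning (drop any included
predictor whose p rises above .10); both thresholds are arguments and are
echoed in the step log. Note a structural property of this procedure:
with 12 candidates screened at α = .05, some spurious co-entry alongside
a true predictor is expected in roughly 40% of null-plus-one-signal
datasets — the reliable guarantees are that a strong true predictor
enters, and enters first.

## The synthetic generator: what it emulates, and what it does not

Joint-angle channels are: a neutral stance posture, plus a
participant-level baseline deviation (Gaussian, SD 1.5°, shared across
that participant's trials), plus a signed CAI−HC offset pattern, plus —
moving condition only — a platform-entrained sinusoid at 1.6 Hz with
frontal-plane-dominant amplitudes and a distal-to-proximal phase lag,
plus stationary AR(1) noise (coefficient 0.95 at 100 Hz, marginal SD 1°;
physiological sway is low-frequency dominated and the colouring reflects
that). The default offset pattern follows the described CAI strategy
(more dorsiflexed ankle, more flexed knee, less flexed hip and torso,
more adducted hip, internally rotated ankle, externally rotated knee and
hip, less externally rotated torso) with magnitudes of 0.5–1.0°, sized to
give a matched-component score separation of d ≈ 1.2–1.5 at 23 per group
— a strong, detectable design effect.

Markers are exact rigid-body forward kinematics of the planted angles
over a five-segment stick body (foot 0.25 x 0.10 m — 10 cm matching an
average foot width — shank 0.40 m, thigh 0.40 m, pelvis 0.25 m, torso
0.50 m, all overridable), the foot translating with the platform, with
optional 0.5 mm Gaussian marker noise (the default). The angle-extraction
stage recovers planted tensors to < 1e−6° noise-free — a round-trip
oracle for the whole kinematic chain.

The COP is a mean-reverting Ornstein–Uhlenbeck path (reversion 8 s⁻¹)
low-pass filtered at 3 Hz, inside the foot rectangle. Group and condition
effects enter as a velocity scale applied as an exact time-rescaling of
that law: positions keep their marginal spread (ML SD 8 mm) while every
velocity scales by k, and the spectral support (3 Hz x k) stays below the
10 Hz analysis filter, so planted TTB contrasts survive conditioning.
Default scales — CAI/HC 1.5/1.0 static, 3.7/3.5 moving — reproduce the
canonical pattern for this population: a CAI deficit in static stance
only, both groups far less stable on the moving platform, i.e. a large
group-by-condition interaction on all TTB minima summaries. Forces and
moments are constructed so the COP formula inverts to the planted COP
exactly (a constructed-inverse oracle); vertical load is ~700 N with
small coloured fluctuations.

What passing tests therefore show: the pipeline's operations are
individually correct against oracles, the end-to-end chain recovers
planted kinematic and kinetic structure at realistic noise levels, group
tests are calibrated (null cohorts reject at the nominal 5% within ±2
points) and powered (planted offsets detected in ≥ 90% of seeded runs).
What they do not show: anything about muscle activity, co-contraction, or
the specific component indices, correlations (e.g. score–SDAmp), or
regression R² values one would obtain on real human cohorts — the
generator plants no coupling between kinematic patterns and balance
metrics, and the acceptance script consequently reports near-zero values
for those quantities, honestly.

## Problem sizes and determinism

Cohort generation and analysis are deterministic given the seed. The
full-size path (46 participants, 276 trials, 46 x 12,000 matrices, 46
surrogate refits) is exercised once in the dimensionality checks and in
`scripts/acceptance.py` (~20 s total). Monte-Carlo calibration and power
checks run many replicate cohorts at reduced waveform resolution (15–25
Hz sampling) and, for calibration, 12 per group: rejection rates and
score-space effect sizes do not depend on waveform resolution, and this
keeps hundreds of replicates inside a test suite that runs in about a
minute.

## Known limitations

- No musculoskeletal or forward-dynamics realism: forces satisfy only the
  COP-consistency contract; no joint moments, centre-of-mass estimation,
  or anteroposterior TTB.
- The rectangle boundary is anatomically crude (bounding box of four
  trial-averaged markers); real feet are not rectangles.
- Whether the original TTB analyses capped or excluded near-zero-velocity
  samples, and their exact minima definition, are not standardised in the
  field; both are configurable here and the defaults are documented above.
- The Bonferroni family for the post hocs (m = 2 per framing) is one
  defensible choice among several; it is configurable.
- C3D input is not parsed; TRC and wide-CSV readers cover the interchange
  formats, behind an interface a C3D reader could later join.
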