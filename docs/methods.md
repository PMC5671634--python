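# Methods

This note documents the models, defaults and design choices behind the
simulation, and what the passing tests do and do not establish.

## Synthetic EEG

Real motor-imagery EEG is replaced by the simplest generative process
that carries the contrast the decoder exploits. Each channel is the sum
of

- a **mu rhythm**: white Gaussian noise band-passed to 8–12 Hz
  (4th-order Butterworth) and normalised to unit RMS, scaled by
  `mu_amplitude` (default 1.0); and
- **broadband background noise**: white noise through a one-pole
  low-pass (cutoff ≈ 8 Hz, a 1/f-flavoured spectrum), normalised to RMS
  `noise_sigma` (default 0.35).

During motor imagery the mu amplitude on the `modulated_channels`
(defaults: indices 3, 10, 2, 11 — the FC5, FC6, F3, F4 positions of a
14-channel consumer montage, i.e. bilateral sensorimotor-adjacent
sites) is multiplied by `1 − erd_depth`, so mu **power** drops by
`(1 − erd_depth)²`; the default `erd_depth = 0.5` gives a 4:1 rest/MI
power ratio. `erd_depth` and `noise_sigma` were calibrated once so that
the default 40-trial session cross-validates comfortably above the
mid-80s-percent aggregate accuracy typical of consumer-grade
motor-imagery BMIs, and then frozen; they are not subject
physiology. Sessions follow the cued-protocol structure: a random order
of 20 motor-imagery and 20 rest trials, 4-s task blocks, uniform 1–3-s
uncued intervals that are excluded from training.

What this generator deliberately omits: ocular/muscular artifacts, line
noise, channel correlation structure, nonstationarity across a session,
and subject variability. Passing decoder tests therefore demonstrate
the correctness of the chain (filtering, CSP algebra, fold hygiene,
trigger semantics) and its behaviour under a controlled ERD contrast —
not performance on human EEG.

## Decoding chain

- **Filtering** is causal (forward-only) IIR, second-order sections,
  shared between training and online paths, because the modelled system
  is real-time; filter state is continuous over a stream, and windows
  are cut from the filtered stream.
- **Windows**: 1 s long, 62.5-ms steps (128 and 8 samples at 128 Hz).
  Training windows are cut from within the 4-s task blocks only and
  inherit the block label.
- **CSP** uses per-epoch covariances normalised by trace, averaged per
  class, with a ridge term `1e-6 · trace/n · I` for rank safety. The
  generalized eigenproblem is solved on whole 4-s epochs (cleaner
  covariance estimates than 1-s windows); `n_pairs = 3` filter pairs
  are retained from the spectral extremes, a common BCI default.
- **LDA** is the pooled-covariance Fisher discriminant
  (scikit-learn's `lsqr` solver), scores positive toward motor imagery.
- **Action power** maps the LDA score through a logistic
  `1 / (1 + exp(−s/σ))` with `σ` the standard deviation of the training
  scores. Any monotone map onto [0, 1] with 0.5 at the boundary is
  admissible here; the logistic is the conventional choice. The trigger
  threshold is 0.60, compared **strictly** (`p > 0.60`).
- **Cross-validation** is trial-stratified (all windows of a trial stay
  in one fold) and refits CSP + LDA inside each training fold;
  accuracies are window-level. Class predictions during CV use the
  0.5 decision boundary; 0.60 is the online trigger threshold, chosen
  to trade false positives against responsiveness, not the classifier
  boundary.

## Gaze and vision

Gaze is smoothed by a 10-point moving average (averaging over the
samples available during warm-up) and resampled to the 30-ms cursor
cadence with a zero-order hold (updates at `k · 30 ms` while not past
the last sample). Hit regions are the axis-aligned bounding boxes of
segmented objects, matching the highlight rectangle a user would see;
containment ties break to the nearest centroid. Highlighting is
instantaneous on containment (no dwell requirement).

Conventions fixed repo-wide: pixel origin top-left, x right, y down;
robot frame in mm, origin at workspace corner P1, x right, y up, z up
from the table; object angles in degrees in [−90, 90), robot-frame
sense. Segmentation converts RGB→HSV and thresholds generous hue bands
around the pure primaries (±30°, saturation ≥ 0.3, value ≥ 0.2),
keeping connected components of ≥ 50 px. The pixel↔robot map is the
exact 4-point DLT homography of the 150 × 150 mm workspace corners
(p1–p4 ↔ P1–P4). Camera pose from the square marker at the world origin
is the closed-form planar-PnP homography decomposition
(`H = K [r₁ r₂ t]` up to scale, rotation orthonormalised by SVD); the
simulated camera is an ideal pinhole, distortion-free. The marker width
defaults to the configured 1 mm and is freely configurable; note that a
1-mm marker is implausibly small next to 10 × 20 × 10 mm cuboids, so
tests and examples use a 40-mm marker. The scene render is a top-down
orthographic view used for segmentation targets; PnP tests synthesise
their own perspective views, decoupling the two error budgets.

## AR feedback and state machine

The grasp predicate — aperture **strictly** below object width — is one
shared function used by both the force arrows and the FSM's holding
state; the safety predicate — height **strictly** above the 15-mm
obstacle — drives the height box. Arrow length is
`c · (width − aperture + over-closure)` with `c = 1` mm/mm by default.
The aperture box sits at a configurable offset beside the object
(default +15 mm in x).

The gripper opens to 25 mm initially; each validated grasp trigger
closes it 1 mm, floored at 0 mm, after which further triggers increment
a separate over-closure counter (the physical jaws stop; the commanded
force keeps rising). Lift triggers raise z by 1 mm from the z = 0 grasp
pose (table level). Reaching, delivering (constant-height path) and the
return home are autonomous segments at 50 mm/s; the robot is busy for
`distance / speed` and consumes no triggers meanwhile. The servo map is
a monotone cubic (PCHIP) through six calibration samples spanning
0–25 mm aperture (coefficients are configuration; the shipped samples
have the decreasing, gently curved shape of a linkage gripper), with
the inverse obtained by bracketed root finding. Releasing is modelled
as arrival at the target area followed by one trigger.

## Simulated users and the study

The user policy closes the loop at the 62.5-ms tick cadence. It fixates
the current target (object, G-circle, or colour-matched target area)
with 2-px Gaussian gaze jitter through the smoothing filter, and holds
motor imagery only while the smoothed cursor is on the intended element
(no triggering mid-saccade). In the **AR** condition the policy stops
closing/lifting at the first tick where the overlay criterion fires
(arrows visible; height box safe) plus a per-event reaction lag of 0–2
extra triggers (uniform). In the **visual-only** condition the policy
continues to its noisy internal perception of the same criterion:
grasp-extra triggers ~ TruncNormal(9, 4, min 0) rounded, lift overshoot
~ TruncNormal(9, 3, min 2) mm beyond the obstacle. These overshoot
distributions are explicitly fictional calibrations whose scale echoes
human visual-inspection behaviour; they are configuration, not claims
about subjects.

Triggers come from an ideal intent→trigger channel by default, or from
`DecoderTriggerSource`, which decodes pre-generated pure-MI and
pure-rest synthetic streams once and replays the decoded trigger
sequence matching the current intent — injecting real decoder false
positives and misses into the loop at negligible cost.

A session interleaves 15 AR and 15 visual-only trials in seeded random
order over a static three-cuboid scene (segmented once per session).
Indices per trial: grasp-phase and lift-phase trigger counts and the
height gap (final lift z − 15 mm). Conditions are compared with the
one-tailed Wilcoxon rank-sum test (AR < NoAR for all three indices),
exact by enumeration when min(n, m) ≤ 8 without ties, else the
continuity-corrected normal approximation; at n = 15 per condition the
approximation applies.

## Problem sizes and numerical choices

Default problem sizes used throughout tests and the acceptance script:
40-trial sessions (≈ 236 s of 14-channel 128-Hz EEG), 5-fold CV,
15 + 15-trial studies, 100 random camera poses for reprojection checks,
100 seeded studies for the significance-rate property. A full CV runs
in well under a second and a full study in about half a second, so the
whole suite is interactive. Tolerances: CSP whitening 1e−6, eigenvalue
complementarity 1e−8, homography corner reproduction 1e−8, projective
round-trip 1e−9, PnP reprojection 0.5 px, segmentation 1 px / 2°,
servo-map inverse 0.1 mm. Degenerate inputs (zero-variance windows,
collinear calibration corners, points behind the camera, empty
timelines) raise typed errors rather than propagating NaNs.

## Known limitations

- The EEG generator's independence across channels makes CSP's job
  easier than on real data; accuracy numbers characterise the pipeline
  under the stated contrast, not human performance.
- The eight human participants of a physical study are replaced by two
  parameterised policies; between-subject variability is represented
  only through seed-to-seed sampling noise.
- No contact physics: grasp success is a geometric predicate, and
  over-closure accumulates as a counter rather than deforming anything.
- The marker-pose path and the orthographic scene render use separate
  camera models by design; there is no end-to-end perspective video
  loop.
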