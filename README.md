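# gazebmi

A fully simulated, closed-loop **hybrid gaze–BMI** robotic-arm control
system with **augmented-reality (AR) feedback**, runnable headless on
synthetic data.

Severely paralysed users can operate an assistive robotic arm through a
non-invasive brain–machine interface, but grasping and lifting are hard
to control with visual inspection alone. In the hybrid scheme modelled
here, *gaze* selects the spatial target and a two-class *motor-imagery*
EEG decoder gates every action: a validated "trigger command" confirms
the selected object, switches action phases, and steps the gripper
aperture or height in 1-mm quanta. AR overlays — a box showing the
gripper aperture, arrows showing the simulated grasp force, and a box
showing the gripper altitude against a 15-mm obstacle — close the visual
loop during the manual grasping and lifting phases. The package lets you
measure, end to end and entirely in software, how much that feedback
reduces user effort (trigger-command counts) and improves precision (the
lift *height gap*).

## What is inside

| Module | Contents |
| --- | --- |
| `gazebmi.synthetic_data` | Generators for cued motor-imagery EEG sessions (14 ch, 128 Hz, mu-band ERD), 60-Hz gaze streams and top-down workspace scenes with ground truth |
| `gazebmi.eeg_decoding` | Causal 5th-order Butterworth 8–12 Hz band-pass, 1-s/62.5-ms sliding windows, CSP, Fisher LDA, action power in [0, 1], strict 0.60-threshold triggers, trial-stratified cross-validation |
| `gazebmi.gaze_tracking` | 10-point moving-average smoothing, 30-ms cursor resampling, object/UI hit testing |
| `gazebmi.workspace_vision` | HSV colour segmentation, exact 4-point pixel↔robot homography (DLT), planar-marker PnP camera pose, pinhole projection |
| `gazebmi.ar_feedback` | Aperture box, grasp-force arrows, lift-height box; optional 2-D rasterisation |
| `gazebmi.manipulation_fsm` | REACH→GRASP→LIFT→DELIVER→RELEASE→DONE shared-control state machine, simulated end-point arm, servo-angle map |
| `gazebmi.experiment` | Simulated user policies, AR vs no-AR sessions, one-tailed Wilcoxon rank-sum comparisons |

The decoder components follow the scikit-learn estimator protocol
(`CSP` is a transformer, `MotorImageryDecoder` a classifier), so they
compose with sklearn pipelines and model selection.

## The decoding model

With band-passed epochs of the two classes (rest / motor imagery), CSP
solves the generalized eigenproblem

```
C_mi w = λ (C_rest + C_mi) w
```

on trace-normalised average class covariances and keeps the three filter
pairs from the spectral extremes. A window `X` maps to features
`f_i = log(var(w_i X) / Σ_j var(w_j X))`, classified by Fisher LDA
(`s = wᵀf + b`); a logistic squashing of `s`, scaled by the training
scores' standard deviation, yields the *action power* `p ∈ [0, 1]` with
`p = 0.5` at the decision boundary. A trigger command is emitted iff
`p > 0.60` (strict), at the 62.5-ms window cadence; while the robot is
executing an autonomous segment every trigger is ignored.

## Worked example

```python
from gazebmi import SynthEEGConfig, generate_training_session, crossvalidate
from gazebmi.experiment import run_session

session = generate_training_session(SynthEEGConfig(seed=42), n_trials_per_class=20)
cv = crossvalidate(session, k=5, seed=42)
print(f"5-fold CV accuracy: {100 * cv.accuracy_total:.2f}%")

study = run_session(n_per_condition=15, seed=7)
print(f"AR   mean height gap: {study.ar.mean_height_gap_mm:.2f} mm")
print(f"NoAR mean height gap: {study.no_ar.mean_height_gap_mm:.2f} mm")
print(f"one-sided rank-sum p: {study.tests['height_gap_mm']['p']:.2g}")
```

prints

```
5-fold CV accuracy: 95.36%
AR   mean height gap: 1.73 mm
NoAR mean height gap: 11.40 mm
one-sided rank-sum p: 1.3e-06
```

The decoder separates the two mental states well above chance on the
default synthetic session; over 15 + 15 simulated trials the AR-guided
user stops lifting within ~2 mm of the minimum safe height, while the
visual-only user overshoots by ~11 mm on average, a highly significant
difference.

A thin CLI mirrors the pipeline:

```bash
gazebmi synth eeg --seed 1 --out sess/
gazebmi train-decoder --session sess/ --out model.json
gazebmi run-study --seed 7 --out results/
```

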