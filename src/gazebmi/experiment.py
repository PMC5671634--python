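"""Closed-loop evaluation: simulated users, AR vs no-AR sessions, metrics.

A simulated user policy stands in for the human participant.  In the AR
condition it stops issuing grasp/lift triggers as soon as the relevant
overlay criterion fires (force arrows visible; height box safe), plus a
small reaction lag.  In the visual-only condition it keeps triggering
until its noisy internal perception of the same criterion is met,
sampled per trial from calibrated overshoot distributions.  Metrics per
trial are the trigger-command counts in the grasping and lifting phases
and the lift height gap (final gripper altitude minus obstacle height);
conditions are compared with the one-tailed Wilcoxon rank-sum test.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import ar_feedback
from .eeg_decoding import MotorImageryDecoder
from .gaze_tracking import Selection, UIElement, hit_test
from .manipulation_fsm import ArmConfig, Phase, SystemState, step
from .synthetic_data import (
    MOTOR_IMAGERY,
    REST,
    SceneSpec,
    SynthEEGConfig,
    default_scene,
    generate_eeg_stream,
    render_workspace_scene,
)
from .workspace_vision import WorkspaceObject, segment_cuboids

AR = "AR"
NO_AR = "NoAR"

TICK_S = 0.0625  # trigger cadence


@dataclass(frozen=True)
class UserPolicy:
    """Simulated-user parameters.

    ``reaction_lag_triggers`` extra triggers are issued after the stop
    criterion is perceived (sampled uniformly from 0..max per stop event).
    The visual-only overshoots are explicitly fictional calibrations whose
    scale echoes human no-AR behaviour; they are configuration, not claims.
    """

    mode: str = "ar_guided"  # "ar_guided" | "visual_only"
    reaction_lag_max: int = 2
    lift_overshoot_mean_mm: float = 9.0
    lift_overshoot_sd_mm: float = 3.0
    lift_overshoot_min_mm: float = 2.0
    grasp_extra_mean: float = 9.0
    grasp_extra_sd: float = 4.0
    grasp_extra_min: float = 0.0

    def sample_reaction_lag(self, rng) -> int:
        return int(rng.integers(0, self.reaction_lag_max + 1))

    def sample_lift_overshoot(self, rng) -> float:
        return max(self.lift_overshoot_min_mm,
                   rng.normal(self.lift_overshoot_mean_mm, self.lift_overshoot_sd_mm))

    def sample_grasp_extra(self, rng) -> int:
        return int(round(max(self.grasp_extra_min,
                             rng.normal(self.grasp_extra_mean, self.grasp_extra_sd))))


@dataclass(frozen=True)
class TrialResult:
    condition: str
    target_color: str
    commands_grasp: int
    commands_lift: int
    height_gap_mm: float
    success: bool
    log: tuple = ()


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    results: tuple[TrialResult, ...]
    mean_commands_grasp: float
    sd_commands_grasp: float
    mean_commands_lift: float
    sd_commands_lift: float
    mean_height_gap_mm: float
    sd_height_gap_mm: float


@dataclass(frozen=True)
class StudyResult:
    ar: ConditionSummary
    no_ar: ConditionSummary
    tests: dict  # index -> {"statistic": W, "p": p, "method": ...}


# ---------------------------------------------------------------------------
# Trigger sources


class IdealTriggerSource:
    """Intent maps one-to-one onto triggers (protocol-level evaluation)."""

    def wants_trigger(self, intend_mi: bool) -> bool:
        return intend_mi


class DecoderTriggerSource:
    """Routes intents through the synthetic-EEG -> decoder chain.

    Two long streams (pure motor imagery / pure rest) are generated with
    the user's EEG configuration and decoded once; ticks then consume the
    decoded trigger sequence matching the current intent, so decoder
    false positives and missed detections enter the loop.
    """

    def __init__(self, decoder: MotorImageryDecoder, eeg_config: SynthEEGConfig,
                 rng, stream_s: float = 60.0):
        self._seq = {}
        self._pos = {MOTOR_IMAGERY: 0, REST: 0}
        for state in (MOTOR_IMAGERY, REST):
            stream = generate_eeg_stream(eeg_config, [(state, stream_s)], rng=rng)
            outputs, _ = decoder.decode(stream)
            self._seq[state] = np.array([o.action_power > decoder.threshold for o in outputs])

    def wants_trigger(self, intend_mi: bool) -> bool:
        state = MOTOR_IMAGERY if intend_mi else REST
        seq = self._seq[state]
        v = bool(seq[self._pos[state] % len(seq)])
        self._pos[state] += 1
        return v


# ---------------------------------------------------------------------------
# Trial runner


@dataclass(frozen=True)
class _Trigger:
    t_s: float


def default_ui_layout(scene: SceneSpec) -> list[UIElement]:
    """GUI circles at the bottom of the screen plus the coloured target
    areas rendered at their workspace positions."""
    w, h = scene.image_size
    ui = [
        UIElement("G_circle", (w / 2 - 40, h - 60, w / 2 + 40, h - 10)),
        UIElement("M_circle", (w / 2 + 60, h - 60, w / 2 + 140, h - 10)),
    ]
    for color, center in scene.target_areas:
        cx, cy = scene.mm_to_px(center)
        ui.append(UIElement(f"target_area:{color}", (cx - 40, cy - 25, cx + 40, cy + 25)))
    return ui


class _GazeSimulator:
    """Jittered fixation -> 10-point moving average, one sample per tick."""

    def __init__(self, rng, jitter_sigma: float = 2.0, window: int = 10):
        self.rng = rng
        self.sigma = jitter_sigma
        self.buf: deque = deque(maxlen=window)

    def look_at(self, point_px) -> tuple[float, float]:
        x = point_px[0] + self.rng.normal(0, self.sigma)
        y = point_px[1] + self.rng.normal(0, self.sigma)
        self.buf.append((x, y))
        arr = np.asarray(self.buf)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _ui_center(ui: list[UIElement], name: str) -> tuple[float, float]:
    for u in ui:
        if u.name == name:
            x0, y0, x1, y1 = u.bbox_px
            return ((x0 + x1) / 2, (y0 + y1) / 2)
    raise ValueError(f"no UI element {name!r}")


def run_trial(
    policy: UserPolicy,
    condition: str,
    scene: SceneSpec | None = None,
    trigger_source=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    target_color: str = "red",
    objects: list[WorkspaceObject] | None = None,
    arm_config: ArmConfig | None = None,
    command_budget: int = 200,
    keep_log: bool = False,
) -> TrialResult:
    """Drive the state machine from REACH to DONE under one condition.

    The policy fixates (with gaze jitter and smoothing), issues intent at
    the 62.5-ms tick cadence, and stops each manual phase per its
    condition: at the AR overlay criterion plus reaction lag, or at its
    sampled visual-only perception of the same criterion.
    """
    if condition not in (AR, NO_AR):
        raise ValueError(f"condition must be {AR!r} or {NO_AR!r}")
    scene = scene or default_scene()
    rng = rng if rng is not None else np.random.default_rng(seed)
    trigger_source = trigger_source or IdealTriggerSource()
    if objects is None:
        image, _ = render_workspace_scene(scene)
        objects = segment_cuboids(image)
    target_obj = next(o for o in objects if o.color == target_color)
    width = target_obj.width_mm
    ui = default_ui_layout(scene)
    cfg = arm_config or ArmConfig(obstacle_mm=scene.obstacle_height_mm,
                                  workspace_mm=scene.workspace_mm)
    state = SystemState(config=cfg)
    gaze = _GazeSimulator(rng)

    lag_grasp = policy.sample_reaction_lag(rng)
    lag_lift = policy.sample_reaction_lag(rng)
    if condition == NO_AR:
        grasp_stop_commands = (cfg.aperture_init_mm - width + 1) + policy.sample_grasp_extra(rng)
        lift_stop_z = cfg.obstacle_mm + policy.sample_lift_overshoot(rng)
    else:
        grasp_stop_commands = lift_stop_z = None

    lag_left = {"grasp": lag_grasp, "lift": lag_lift}
    t = 0.0
    issued = 0
    success = False
    max_duration_s = 300.0
    while issued < command_budget and t < max_duration_s:
        t += TICK_S
        if state.is_busy_at(t):
            continue
        phase = state.phase
        if phase in (Phase.RELEASE, Phase.DONE):
            success = True
            break

        # Decide what the user wants to look at this tick.
        lag_key = None
        if phase is Phase.REACH:
            fix_point, want = target_obj.centroid_px, "object"
        elif phase is Phase.GRASP:
            if condition == AR:
                arrows = ar_feedback.force_arrows(width, state.gripper.aperture_mm,
                                                  over_closure_mm=state.over_closure_mm)
                done_closing = arrows.visible
            else:
                done_closing = state.commands_grasp >= grasp_stop_commands
            if done_closing and lag_left["grasp"] <= 0:
                fix_point, want = _ui_center(ui, "G_circle"), "G_circle"
            else:
                fix_point, want = target_obj.centroid_px, "object"
                if done_closing:
                    lag_key = "grasp"  # this trigger is a reaction-lag extra
        elif phase is Phase.LIFT:
            if condition == AR:
                hbox = ar_feedback.height_box(state.gripper.z_mm,
                                              obstacle_height_mm=cfg.obstacle_mm)
                high_enough = hbox.safe
            else:
                high_enough = state.gripper.z_mm >= lift_stop_z
            if high_enough and lag_left["lift"] <= 0:
                fix_point, want = _ui_center(ui, f"target_area:{target_color}"), "target_area"
            else:
                fix_point, want = target_obj.centroid_px, "object"
                if high_enough:
                    lag_key = "lift"
        else:  # DELIVER: arrived; one trigger releases, selection irrelevant
            fix_point, want = _ui_center(ui, f"target_area:{target_color}"), "any"

        cursor = gaze.look_at(fix_point)
        selection = hit_test(cursor, objects, ui)

        # The user holds motor imagery only once the smoothed cursor has
        # settled on the intended element (no triggering mid-saccade).
        if want == "object":
            on_target = (selection.kind == "object"
                         and selection.target.object_id == target_obj.object_id)
        elif want == "G_circle":
            on_target = selection.kind == "ui" and selection.target == "G_circle"
        elif want == "target_area":
            on_target = (selection.kind == "ui"
                         and selection.target == f"target_area:{target_color}")
        else:
            on_target = True

        trig = None
        if trigger_source.wants_trigger(on_target):
            trig = _Trigger(t_s=t)
            issued += 1
            if lag_key is not None and on_target:
                lag_left[lag_key] -= 1
        step(state, selection, trig, scene, t_s=t)

    success = success or state.phase in (Phase.RELEASE, Phase.DONE)
    final_z = state.commands_lift * cfg.step_mm  # z datum 0 at the grasp pose
    gap = final_z - cfg.obstacle_mm
    return TrialResult(
        condition=condition,
        target_color=target_color,
        commands_grasp=state.commands_grasp,
        commands_lift=state.commands_lift,
        height_gap_mm=gap,
        success=success and gap > 0,
        log=tuple(state.command_log) if keep_log else (),
    )


# ---------------------------------------------------------------------------
# Sessions and statistics


def _summarize(condition: str, results: list[TrialResult]) -> ConditionSummary:
    g = np.array([r.commands_grasp for r in results], dtype=float)
    l = np.array([r.commands_lift for r in results], dtype=float)
    h = np.array([r.height_gap_mm for r in results], dtype=float)
    return ConditionSummary(
        condition=condition,
        results=tuple(results),
        mean_commands_grasp=float(g.mean()), sd_commands_grasp=float(g.std(ddof=1)) if len(g) > 1 else 0.0,
        mean_commands_lift=float(l.mean()), sd_commands_lift=float(l.std(ddof=1)) if len(l) > 1 else 0.0,
        mean_height_gap_mm=float(h.mean()), sd_height_gap_mm=float(h.std(ddof=1)) if len(h) > 1 else 0.0,
    )


def wilcoxon_rank_sum(sample_a, sample_b, alternative: str = "less") -> dict:
    """One-tailed Wilcoxon rank-sum test (midrank ties).

    Exact p by enumeration when min(n, m) <= 8 and there are no ties,
    normal approximation with continuity correction otherwise.  Returns
    the rank-sum statistic W of ``sample_a``, the p-value, the method
    used, and a flag when the samples are wholly uninformative.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"statistic": float(stats.rankdata(pooled)[: len(a)].sum()),
                "p": 1.0, "method": "degenerate", "flag": "all values identical"}
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(a), len(b)) <= 8 and not has_ties
    res = stats.mannwhitneyu(a, b, alternative=alternative,
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    W = float(res.statistic + len(a) * (len(a) + 1) / 2)  # U -> rank sum
    return {"statistic": W, "p": float(res.pvalue),
            "method": "exact" if exact else "normal_approx", "flag": None}


def run_session(
    n_per_condition: int = 15,
    policy_ar: UserPolicy | None = None,
    policy_no_ar: UserPolicy | None = None,
    scene: SceneSpec | None = None,
    seed: int | None = None,
    trigger_source=None,
    keep_logs: bool = False,
) -> StudyResult:
    """A full evaluation session: randomly interleaved AR / no-AR trials,
    per-condition summaries, and one-tailed rank-sum tests (AR < NoAR)
    for each index."""
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    policy_ar = policy_ar or UserPolicy(mode="ar_guided")
    policy_no_ar = policy_no_ar or UserPolicy(mode="visual_only")
    scene = scene or default_scene()
    rng = np.random.default_rng(seed)

    image, _ = render_workspace_scene(scene)
    objects = segment_cuboids(image)
    colors = [c.color for c in scene.cuboids]

    order = [AR] * n_per_condition + [NO_AR] * n_per_condition
    rng.shuffle(order)
    results = {AR: [], NO_AR: []}
    for cond in order:
        policy = policy_ar if cond == AR else policy_no_ar
        color = colors[int(rng.integers(len(colors)))]
        results[cond].append(
            run_trial(policy, cond, scene=scene, rng=rng, target_color=color,
                      objects=objects, trigger_source=trigger_source, keep_log=keep_logs)
        )

    ar_sum = _summarize(AR, results[AR])
    no_ar_sum = _summarize(NO_AR, results[NO_AR])
    tests = {}
    for index, attr in (("commands_grasp", "commands_grasp"),
                        ("commands_lift", "commands_lift"),
                        ("height_gap_mm", "height_gap_mm")):
        a = [getattr(r, attr) for r in results[AR]]
        b = [getattr(r, attr) for r in results[NO_AR]]
        tests[index] = wilcoxon_rank_sum(a, b, alternative="less")
    return StudyResult(ar=ar_sum, no_ar=no_ar_sum, tests=tests)


def report(study: StudyResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial table and per-condition summary table (bar-chart data)."""
    rows = []
    for summary in (study.ar, study.no_ar):
        for i, r in enumerate(summary.results):
            rows.append({"condition": r.condition, "trial": i, "target_color": r.target_color,
                         "commands_grasp": r.commands_grasp, "commands_lift": r.commands_lift,
                         "height_gap_mm": r.height_gap_mm, "success": r.success})
    trials = pd.DataFrame(rows)
    summary_rows = []
    for s in (study.ar, study.no_ar):
        summary_rows.append({
            "condition": s.condition,
            "mean_commands_grasp": s.mean_commands_grasp, "sd_commands_grasp": s.sd_commands_grasp,
            "mean_commands_lift": s.mean_commands_lift, "sd_commands_lift": s.sd_commands_lift,
            "mean_height_gap_mm": s.mean_height_gap_mm, "sd_height_gap_mm": s.sd_height_gap_mm,
        })
    return trials, pd.DataFrame(summary_rows)
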