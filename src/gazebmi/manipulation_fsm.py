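"""Five-phase shared-control state machine and simulated arm.

Manipulation is split into REACH -> GRASP -> LIFT -> DELIVER -> RELEASE
-> DONE.  Reaching, delivering and releasing are autonomous robot
segments started by a single validated trigger; grasping and lifting are
manual, one 1-mm quantum of aperture or height per trigger.  While the
arm is executing an autonomous segment (robot busy) every trigger is
logged and ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .ar_feedback import is_grasped
from .gaze_tracking import Selection
from .synthetic_data import SceneSpec
from .workspace_vision import Homography, WorkspaceObject, pixel_to_robot


class FSMError(ValueError):
    pass


class Phase(Enum):
    REACH = "REACH"
    GRASP = "GRASP"
    LIFT = "LIFT"
    DELIVER = "DELIVER"
    RELEASE = "RELEASE"
    DONE = "DONE"


@dataclass(frozen=True)
class ArmConfig:
    aperture_init_mm: float = 25.0
    aperture_min_mm: float = 0.0
    step_mm: float = 1.0
    obstacle_mm: float = 15.0
    workspace_mm: float = 150.0
    speed_mm_s: float = 50.0
    approach_height_mm: float = 30.0
    home_xy_mm: tuple[float, float] = (75.0, 0.0)
    threshold: float = 0.60


@dataclass
class GripperState:
    aperture_mm: float = 25.0
    z_mm: float = 0.0
    xy_mm: tuple[float, float] = (75.0, 0.0)
    jaw_angle_deg: float = 0.0
    holding: int | None = None


@dataclass(frozen=True)
class LogEntry:
    t_s: float
    phase: str
    event: str
    aperture_mm: float
    z_mm: float
    x_mm: float
    y_mm: float


@dataclass
class SystemState:
    """The controlled plant: phase, gripper, selection and the append-only
    command log."""

    config: ArmConfig = field(default_factory=ArmConfig)
    phase: Phase = Phase.REACH
    gripper: GripperState = field(default=None)  # type: ignore[assignment]
    selected_object: WorkspaceObject | None = None
    highlighted_object: WorkspaceObject | None = None
    over_closure_mm: float = 0.0
    busy_until_s: float = -np.inf
    commands_grasp: int = 0
    commands_lift: int = 0
    command_log: list[LogEntry] = field(default_factory=list)

    def __post_init__(self):
        if self.gripper is None:
            self.gripper = GripperState(
                aperture_mm=self.config.aperture_init_mm, xy_mm=self.config.home_xy_mm
            )

    @property
    def robot_busy(self) -> bool:  # evaluated against the last event time
        return bool(self.command_log) and self.command_log[-1].t_s < self.busy_until_s

    def is_busy_at(self, t_s: float) -> bool:
        return t_s < self.busy_until_s

    def _log(self, t_s: float, event: str) -> None:
        g = self.gripper
        self.command_log.append(
            LogEntry(t_s, self.phase.value, event, g.aperture_mm, g.z_mm, g.xy_mm[0], g.xy_mm[1])
        )


def servo_map_default_samples() -> tuple[tuple[float, float], ...]:
    """Aperture (mm) -> servo angle (deg) calibration samples with the
    decreasing, gently curved shape of a linkage gripper."""
    return ((0.0, 86.0), (5.0, 70.0), (10.0, 52.0), (15.0, 35.0), (20.0, 17.0), (25.0, 0.0))


class ServoMap:
    """Strictly monotone aperture <-> servo-angle map fitted with a
    monotone cubic (PCHIP) through calibration samples; the inverse is
    solved by bracketed root finding so the round trip is exact to well
    below 0.1 mm."""

    def __init__(self, calibration_samples=None):
        samples = sorted(calibration_samples or servo_map_default_samples())
        ap = np.array([s[0] for s in samples], dtype=float)
        ang = np.array([s[1] for s in samples], dtype=float)
        d = np.diff(ang)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise FSMError("calibration samples must be strictly monotone")
        self.samples = tuple(zip(ap, ang))
        self._lo, self._hi = float(ap[0]), float(ap[-1])
        self._interp = PchipInterpolator(ap, ang)

    def angle(self, aperture_mm: float) -> float:
        if not self._lo <= aperture_mm <= self._hi:
            raise FSMError(
                f"aperture {aperture_mm} outside calibration domain [{self._lo}, {self._hi}]"
            )
        return float(self._interp(aperture_mm))

    def aperture(self, angle_deg: float) -> float:
        a, b = float(self._interp(self._lo)), float(self._interp(self._hi))
        lo, hi = min(a, b), max(a, b)
        if not lo <= angle_deg <= hi:
            raise FSMError(f"angle {angle_deg} outside the fitted range [{lo}, {hi}]")
        return float(brentq(lambda x: float(self._interp(x)) - angle_deg,
                            self._lo, self._hi, xtol=1e-9))


def servo_angle(aperture_mm: float, servo_map: ServoMap) -> float:
    return servo_map.angle(aperture_mm)


def simulate_motion(
    state: SystemState,
    destination_xy_mm,
    t_start_s: float = 0.0,
    dt_s: float = 0.0625,
) -> list[tuple[float, float, float]]:
    """Move the simulated end point to ``destination_xy_mm``.

    Sets the busy window (duration = distance / speed), updates the final
    pose, and returns the sampled (t, x, y) path.  A zero-distance move is
    instantaneous and never busy.
    """
    dest = np.asarray(destination_xy_mm, dtype=float)
    ws = state.config.workspace_mm
    if not (0 <= dest[0] <= ws and -ws <= dest[1] <= ws):
        raise FSMError(f"destination {tuple(dest)} outside the workspace")
    start = np.asarray(state.gripper.xy_mm, dtype=float)
    dist = float(np.linalg.norm(dest - start))
    duration = dist / state.config.speed_mm_s
    path = []
    if duration > 0:
        for t in np.arange(0.0, duration, dt_s):
            frac = t / duration
            p = start + frac * (dest - start)
            path.append((t_start_s + t, float(p[0]), float(p[1])))
    path.append((t_start_s + duration, float(dest[0]), float(dest[1])))
    state.gripper.xy_mm = (float(dest[0]), float(dest[1]))
    state.busy_until_s = t_start_s + duration
    return path


def _object_position_mm(obj: WorkspaceObject, scene: SceneSpec,
                        homography: Homography | None) -> np.ndarray:
    if homography is not None:
        return np.asarray(pixel_to_robot(obj.centroid_px, homography), dtype=float)
    return np.asarray(scene.px_to_mm(obj.centroid_px), dtype=float)


def step(
    state: SystemState,
    selection: Selection,
    trigger,
    scene: SceneSpec,
    homography: Homography | None = None,
    t_s: float | None = None,
) -> SystemState:
    """Advance the state machine by one event (mutates and returns ``state``).

    ``selection`` is a gaze hit-test result; ``trigger`` is a TriggerEvent
    or None.  The transition table follows the five-phase protocol; every
    consumed or ignored trigger is logged.
    """
    if selection is None or not hasattr(selection, "kind"):
        raise FSMError("malformed selection")
    t = t_s if t_s is not None else (getattr(trigger, "t_s", None) or 0.0)

    # Highlighting is instantaneous on containment, trigger or not.
    if state.phase is Phase.REACH:
        state.highlighted_object = selection.target if selection.kind == "object" else None

    if trigger is None:
        return state

    if state.is_busy_at(t):
        state._log(t, "ignored_busy")
        return state

    cfg = state.config
    if state.phase is Phase.REACH:
        if state.highlighted_object is None:
            state._log(t, "ignored_no_selection")
            return state
        obj = state.highlighted_object
        state.selected_object = obj
        state.gripper.jaw_angle_deg = obj.angle_deg
        pos = _object_position_mm(obj, scene, homography)
        state._log(t, "confirm")
        simulate_motion(state, pos, t_start_s=t)
        state.gripper.z_mm = 0.0  # grasp-pose datum: table level
        state.phase = Phase.GRASP
        state._log(t, "pre_grasp")
        return state

    if state.phase is Phase.GRASP:
        if selection.kind == "ui" and selection.target == "G_circle":
            state.phase = Phase.LIFT
            state._log(t, "switch_lift")
            return state
        if selection.kind == "object" and state.selected_object is not None \
                and selection.target.object_id == state.selected_object.object_id:
            if state.gripper.aperture_mm - cfg.step_mm >= cfg.aperture_min_mm - 1e-9:
                state.gripper.aperture_mm -= cfg.step_mm
                event = "grasp_step"
            else:
                state.over_closure_mm += cfg.step_mm
                event = "over_closure"
            if is_grasped(state.gripper.aperture_mm, state.selected_object.width_mm):
                state.gripper.holding = state.selected_object.object_id
            state.commands_grasp += 1
            state._log(t, event)
            return state
        state._log(t, "ignored_no_selection")
        return state

    if state.phase is Phase.LIFT:
        if selection.kind == "ui" and str(selection.target).startswith("target_area"):
            state.phase = Phase.DELIVER
            state._log(t, "switch_deliver")
            color = str(selection.target).split(":", 1)[-1]
            dest = _target_area_mm(scene, color)
            simulate_motion(state, dest, t_start_s=t)  # constant-height path
            state._log(t, "deliver_arrived")
            return state
        state.gripper.z_mm += cfg.step_mm
        state.commands_lift += 1
        state._log(t, "lift_step")
        return state

    if state.phase is Phase.DELIVER:
        state.phase = Phase.RELEASE
        state.gripper.holding = None
        state._log(t, "release")
        simulate_motion(state, cfg.home_xy_mm, t_start_s=t)
        state.gripper.z_mm = 0.0
        state.gripper.aperture_mm = cfg.aperture_init_mm
        state.phase = Phase.DONE
        state._log(t, "done")
        return state

    if state.phase in (Phase.RELEASE, Phase.DONE):
        warnings.warn("trigger after task completion ignored", stacklevel=2)
        state._log(t, "ignored_done")
        return state

    raise FSMError(f"unhandled phase {state.phase}")  # pragma: no cover


def _target_area_mm(scene: SceneSpec, color: str) -> tuple[float, float]:
    for c, center in scene.target_areas:
        if c == color:
            return center
    raise FSMError(f"no target area of color {color!r}")


def replay_log(log: list[LogEntry], config: ArmConfig = ArmConfig()) -> dict:
    """Recompute aperture/height/phase trajectory from the command log alone;
    used to audit that state evolves only through validated 1-mm quanta."""
    aperture = config.aperture_init_mm
    z = 0.0
    over_closure = 0.0
    grasp = lift = 0
    phases = []
    for e in log:
        if not phases or phases[-1] != e.phase:
            phases.append(e.phase)
        if e.event == "grasp_step":
            aperture -= config.step_mm
            grasp += 1
        elif e.event == "over_closure":
            over_closure += config.step_mm
            grasp += 1
        elif e.event == "lift_step":
            z += config.step_mm
            lift += 1
        elif e.event == "done":
            aperture = config.aperture_init_mm
            z = 0.0
    return {
        "aperture_mm": aperture,
        "z_mm": z,
        "over_closure_mm": over_closure,
        "commands_grasp": grasp,
        "commands_lift": lift,
        "phase_sequence": phases,
    }
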