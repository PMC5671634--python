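"""Synthetic EEG sessions, gaze streams and workspace scenes.

Everything downstream of the hardware (headset, eye tracker, camera) is
replaced by generators that reproduce the statistical and geometric
structure the pipeline relies on: mu-band (8-12 Hz) event-related
desynchronization over a subset of channels during motor imagery,
fixation jitter in the gaze stream, and pure-colour cuboids of known
pose in a top-down view of the 150 x 150 mm robot workspace.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from skimage.draw import polygon as draw_polygon

# Emotiv EPOC montage order; reference channels excluded.
CHANNEL_NAMES = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

REST = "rest"
MOTOR_IMAGERY = "motor_imagery"

COLORS = ("red", "green", "blue")
_COLOR_RGB = {"red": (255, 0, 0), "green": (0, 255, 0), "blue": (0, 0, 255)}


class ConfigurationError(ValueError):
    """A synthetic-data configuration field is out of range."""


@dataclass(frozen=True)
class SynthEEGConfig:
    """Generative parameters for synthetic motor-imagery EEG.

    The mu rhythm is modelled as band-limited Gaussian noise whose
    amplitude on ``modulated_channels`` is multiplied by
    ``1 - erd_depth`` during motor imagery, so mu-band *power* drops by
    ``(1 - erd_depth)**2``.  Broadband background noise is white noise
    through a one-pole low-pass (1/f-flavoured), scale ``noise_sigma``.
    """

    n_channels: int = 14
    fs: float = 128.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    erd_depth: float = 0.5
    modulated_channels: tuple[int, ...] = (3, 10, 2, 11)  # FC5, FC6, F3, F4
    noise_sigma: float = 0.35
    mu_amplitude: float = 1.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        lo, hi = self.mu_band
        if not 0 < lo < hi:
            raise ConfigurationError(f"mu_band must satisfy 0 < low < high, got {self.mu_band}")
        if self.fs <= 2 * hi:
            raise ConfigurationError(
                f"fs must exceed twice the upper mu_band edge ({2 * hi} Hz), got {self.fs}"
            )
        bad = [c for c in self.modulated_channels if not 0 <= c < self.n_channels]
        if bad:
            raise ConfigurationError(f"modulated_channels out of range: {bad}")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass(frozen=True)
class TrialSchedule:
    """Cue schedule of a training session.

    ``onsets_s[i]`` is the start of the i-th task block; each block lasts
    ``task_duration_s`` and is followed by an uncued inter-trial interval.
    """

    labels: tuple[str, ...]
    onsets_s: tuple[float, ...]
    task_duration_s: float = 4.0

    def __post_init__(self):
        if len(self.labels) != len(self.onsets_s):
            raise ConfigurationError("labels and onsets_s lengths differ")
        if any(b <= a for a, b in zip(self.onsets_s, self.onsets_s[1:])):
            raise ConfigurationError("onsets must be strictly increasing")

    @property
    def end_s(self) -> float:
        return (self.onsets_s[-1] + self.task_duration_s) if self.onsets_s else 0.0

    def trial_sample_slices(self, fs: float) -> list[tuple[str, slice]]:
        n = int(round(self.task_duration_s * fs))
        out = []
        for lab, t0 in zip(self.labels, self.onsets_s):
            i0 = int(round(t0 * fs))
            out.append((lab, slice(i0, i0 + n)))
        return out


@dataclass
class EEGSession:
    """A multichannel recording (channels x samples) with its cue schedule."""

    data: np.ndarray
    fs: float
    schedule: TrialSchedule

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def save(self, directory) -> None:
        """Write the two-file pair: samples CSV + JSON sidecar."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        names = list(CHANNEL_NAMES[: self.n_channels])
        if self.n_channels > len(CHANNEL_NAMES):
            names += [f"CH{i}" for i in range(len(CHANNEL_NAMES), self.n_channels)]
        pd.DataFrame(self.data.T, columns=names).to_csv(d / "eeg.csv", index=False)
        sidecar = {
            "fs": self.fs,
            "labels": list(self.schedule.labels),
            "onsets_s": list(self.schedule.onsets_s),
            "task_duration_s": self.schedule.task_duration_s,
        }
        (d / "eeg.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "EEGSession":
        from pathlib import Path

        d = Path(directory)
        data = pd.read_csv(d / "eeg.csv").to_numpy().T
        meta = json.loads((d / "eeg.json").read_text())
        sched = TrialSchedule(
            labels=tuple(meta["labels"]),
            onsets_s=tuple(meta["onsets_s"]),
            task_duration_s=meta["task_duration_s"],
        )
        return cls(data=np.ascontiguousarray(data, dtype=float), fs=meta["fs"], schedule=sched)


# ---------------------------------------------------------------------------
# EEG generation


def _mu_bandpass_sos(config: SynthEEGConfig):
    lo, hi = config.mu_band
    return signal.butter(4, [lo, hi], btype="bandpass", fs=config.fs, output="sos")


def _background_noise(config: SynthEEGConfig, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Broadband 1/f-ish noise: white noise through a one-pole low-pass, unit RMS
    before scaling by noise_sigma."""
    white = rng.standard_normal((config.n_channels, n_samples))
    # one-pole low-pass y[n] = a*y[n-1] + (1-a)*x[n], cutoff ~ 8 Hz
    a = float(np.exp(-2 * np.pi * 8.0 / config.fs))
    shaped = signal.lfilter([1 - a], [1, -a], white, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return config.noise_sigma * shaped / rms


def _mu_process(config: SynthEEGConfig, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian mu rhythm, unit RMS per channel before envelope."""
    sos = _mu_bandpass_sos(config)
    white = rng.standard_normal((config.n_channels, n_samples))
    mu = signal.sosfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(mu**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return config.mu_amplitude * mu / rms


def _synthesize(config: SynthEEGConfig, mi_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Compose mu + noise with the ERD envelope applied on modulated channels
    wherever mi_mask (per-sample boolean) is true."""
    n = mi_mask.size
    mu = _mu_process(config, n, rng)
    envelope = np.ones((config.n_channels, n))
    if config.modulated_channels:
        idx = np.asarray(config.modulated_channels, dtype=int)
        envelope[np.ix_(idx, np.flatnonzero(mi_mask))] = 1.0 - config.erd_depth
    return mu * envelope + _background_noise(config, n, rng)


def generate_training_session(
    config: SynthEEGConfig = SynthEEGConfig(),
    n_trials_per_class: int = 20,
    inter_trial_range_s: tuple[float, float] = (1.0, 3.0),
    rng: np.random.Generator | None = None,
) -> EEGSession:
    """Generate a cued training session.

    The session is a randomly ordered sequence of ``2 * n_trials_per_class``
    trials, half motor imagery and half rest.  Each task block lasts 4 s and
    is separated from the next by a uniform 1-3 s uncued interval.
    """
    config.validate()
    if n_trials_per_class < 1:
        raise ConfigurationError("n_trials_per_class must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    labels = [MOTOR_IMAGERY] * n_trials_per_class + [REST] * n_trials_per_class
    rng.shuffle(labels)
    lo, hi = inter_trial_range_s
    gaps = rng.uniform(lo, hi, size=len(labels))
    onsets, t = [], 0.0
    for g in gaps:
        onsets.append(t)
        t += 4.0 + g
    schedule = TrialSchedule(labels=tuple(labels), onsets_s=tuple(onsets), task_duration_s=4.0)

    n_samples = int(np.ceil(schedule.end_s * config.fs)) + 1
    mi_mask = np.zeros(n_samples, dtype=bool)
    for lab, sl in schedule.trial_sample_slices(config.fs):
        if lab == MOTOR_IMAGERY:
            mi_mask[sl] = True
    data = _synthesize(config, mi_mask, rng)
    return EEGSession(data=data, fs=config.fs, schedule=schedule)


def generate_eeg_stream(
    config: SynthEEGConfig,
    intent_timeline: list[tuple[str, float]],
    rng: np.random.Generator | None = None,
) -> EEGSession:
    """Continuous recording whose ERD state follows ``intent_timeline``
    (a list of (state, duration_s)); same generative model as the
    training session."""
    config.validate()
    if not intent_timeline:
        raise ConfigurationError("intent_timeline must not be empty")
    for state, dur in intent_timeline:
        if state not in (REST, MOTOR_IMAGERY):
            raise ConfigurationError(f"unknown state {state!r}")
        if dur <= 0:
            raise ConfigurationError("durations must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    segments, labels, onsets, t = [], [], [], 0.0
    for state, dur in intent_timeline:
        n = int(round(dur * config.fs))
        segments.append(np.full(n, state == MOTOR_IMAGERY))
        labels.append(state)
        onsets.append(t)
        t += dur
    mi_mask = np.concatenate(segments)
    data = _synthesize(config, mi_mask, rng)
    # schedule records the timeline; block lengths may differ from 4 s, so
    # task_duration_s is only meaningful for uniform timelines
    schedule = TrialSchedule(
        labels=tuple(labels), onsets_s=tuple(onsets),
        task_duration_s=float(intent_timeline[0][1]),
    )
    return EEGSession(data=data, fs=config.fs, schedule=schedule)


# ---------------------------------------------------------------------------
# Gaze


@dataclass(frozen=True)
class GazeScenario:
    """A sequence of fixations: (target point px, dwell duration s)."""

    fixation_sequence: tuple[tuple[tuple[float, float], float], ...]
    jitter_sigma: float = 3.0
    rate_hz: float = 60.0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ConfigurationError("rate_hz must be positive")
        if self.jitter_sigma < 0:
            raise ConfigurationError("jitter_sigma must be >= 0")
        if not self.fixation_sequence:
            raise ConfigurationError("fixation_sequence must not be empty")
        if any(d <= 0 for _, d in self.fixation_sequence):
            raise ConfigurationError("dwell durations must be positive")


def generate_gaze_stream(scenario: GazeScenario, seed: int | None = None) -> pd.DataFrame:
    """Sample the gaze position at ``rate_hz``: current fixation target plus
    isotropic Gaussian jitter.  Returns a DataFrame with columns t, x, y."""
    scenario.validate()
    rng = np.random.default_rng(seed)
    dt = 1.0 / scenario.rate_hz
    rows = []
    t = 0.0
    for (tx, ty), dwell in scenario.fixation_sequence:
        n = int(round(dwell * scenario.rate_hz))
        jitter = rng.normal(0.0, scenario.jitter_sigma, size=(n, 2))
        for j in range(n):
            rows.append((t, tx + jitter[j, 0], ty + jitter[j, 1]))
            t += dt
    return pd.DataFrame(rows, columns=["t", "x", "y"])


# ---------------------------------------------------------------------------
# Scene


@dataclass(frozen=True)
class CuboidSpec:
    color: str
    center_mm: tuple[float, float]
    angle_deg: float = 0.0
    dims_mm: tuple[float, float, float] = (10.0, 20.0, 10.0)  # W x L x H

    @property
    def width_mm(self) -> float:
        """Graspable width: the short in-plane dimension."""
        return min(self.dims_mm[0], self.dims_mm[1])


@dataclass(frozen=True)
class SceneSpec:
    """Top-down workspace description in robot millimetres.

    The robot frame has its origin at workspace corner P1 (bottom-left in
    the image), x right, y up, z up from the table.  The marker square is
    centred at the workspace centre, which doubles as the AR world origin.
    """

    image_size: tuple[int, int] = (1280, 720)  # (width, height) px
    workspace_mm: float = 150.0
    cuboids: tuple[CuboidSpec, ...] = ()
    marker_width_mm: float = 1.0
    obstacle_height_mm: float = 15.0
    target_areas: tuple[tuple[str, tuple[float, float]], ...] = (
        ("red", (25.0, 135.0)),
        ("green", (75.0, 135.0)),
        ("blue", (125.0, 135.0)),
    )
    px_per_mm: float = 4.0

    def validate(self) -> None:
        for c in self.cuboids:
            if c.color not in COLORS:
                raise ConfigurationError(f"unknown cuboid color {c.color!r}")
            x, y = c.center_mm
            if not (0 <= x <= self.workspace_mm and 0 <= y <= self.workspace_mm):
                raise ConfigurationError(f"cuboid center {c.center_mm} outside workspace")
        if self.marker_width_mm <= 0:
            raise ConfigurationError("marker_width_mm must be positive")

    # -- coordinate transforms -------------------------------------------
    @property
    def _origin_px(self) -> tuple[float, float]:
        """Pixel position of robot-frame origin (workspace corner P1)."""
        w, h = self.image_size
        side = self.workspace_mm * self.px_per_mm
        return ((w - side) / 2.0, (h + side) / 2.0)

    def mm_to_px(self, p_mm) -> np.ndarray:
        """Robot mm (y up) -> pixel (y down)."""
        ox, oy = self._origin_px
        p = np.atleast_2d(np.asarray(p_mm, dtype=float))
        out = np.column_stack(
            (ox + p[:, 0] * self.px_per_mm, oy - p[:, 1] * self.px_per_mm)
        )
        return out if np.ndim(p_mm) > 1 else out[0]

    def px_to_mm(self, p_px) -> np.ndarray:
        ox, oy = self._origin_px
        p = np.atleast_2d(np.asarray(p_px, dtype=float))
        out = np.column_stack(
            ((p[:, 0] - ox) / self.px_per_mm, (oy - p[:, 1]) / self.px_per_mm)
        )
        return out if np.ndim(p_px) > 1 else out[0]

    def workspace_corners_px(self) -> np.ndarray:
        """p1..p4: pixel corners of the workspace square (P1..P4 order)."""
        s = self.workspace_mm
        return np.array([self.mm_to_px((x, y)) for x, y in [(0, 0), (s, 0), (s, s), (0, s)]])

    def workspace_corners_mm(self) -> np.ndarray:
        s = self.workspace_mm
        return np.array([(0.0, 0.0), (s, 0.0), (s, s), (0.0, s)])


def _rect_corners_mm(center, length, width, angle_deg):
    """Corners of a length x width rectangle, long axis along angle_deg
    (CCW from +x in the y-up robot frame)."""
    a = np.deg2rad(angle_deg)
    u = np.array([np.cos(a), np.sin(a)])  # long axis
    v = np.array([-np.sin(a), np.cos(a)])
    c = np.asarray(center, dtype=float)
    hl, hw = length / 2.0, width / 2.0
    return np.array([c + hl * u + hw * v, c - hl * u + hw * v,
                     c - hl * u - hw * v, c + hl * u - hw * v])


def render_workspace_scene(spec: SceneSpec) -> tuple[np.ndarray, list[dict]]:
    """Render the top-down workspace and return (image, ground truth).

    The image is an RGB uint8 array (H x W x 3), grey background with a
    white workspace square, black marker at the workspace centre, and each
    cuboid as a filled rotated rectangle in its pure colour.  Ground truth
    holds, per cuboid, the pixel centroid, in-plane angle (degrees in
    [-90, 90), robot-frame convention), colour and graspable width.
    """
    spec.validate()
    w, h = spec.image_size
    img = np.full((h, w, 3), 64, dtype=np.uint8)

    ws = _rect_corners_mm((spec.workspace_mm / 2, spec.workspace_mm / 2),
                          spec.workspace_mm, spec.workspace_mm, 0.0)
    ws_px = spec.mm_to_px(ws)
    rr, cc = draw_polygon(ws_px[:, 1], ws_px[:, 0], shape=img.shape[:2])
    img[rr, cc] = 255

    centre = (spec.workspace_mm / 2, spec.workspace_mm / 2)
    mk = _rect_corners_mm(centre, spec.marker_width_mm, spec.marker_width_mm, 0.0)
    mk_px = spec.mm_to_px(mk)
    rr, cc = draw_polygon(mk_px[:, 1], mk_px[:, 0], shape=img.shape[:2])
    img[rr, cc] = 0

    ground_truth = []
    occupied = np.zeros(img.shape[:2], dtype=bool)
    for cub in spec.cuboids:
        L = max(cub.dims_mm[0], cub.dims_mm[1])
        W = min(cub.dims_mm[0], cub.dims_mm[1])
        corners_px = spec.mm_to_px(_rect_corners_mm(cub.center_mm, L, W, cub.angle_deg))
        rr, cc = draw_polygon(corners_px[:, 1], corners_px[:, 0], shape=img.shape[:2])
        if occupied[rr, cc].any():
            warnings.warn("overlapping cuboids in scene; rendered in list order", stacklevel=2)
        occupied[rr, cc] = True
        img[rr, cc] = _COLOR_RGB[cub.color]
        angle = ((cub.angle_deg + 90.0) % 180.0) - 90.0
        ground_truth.append(
            {
                "color": cub.color,
                "centroid_px": tuple(np.round(spec.mm_to_px(cub.center_mm), 3)),
                "angle_deg": angle,
                "width_mm": cub.width_mm,
            }
        )
    return img, ground_truth


def default_scene(colors: tuple[str, ...] = ("red", "green", "blue")) -> SceneSpec:
    """A three-cuboid scene with distinct orientations, used throughout the
    tests and the simulated study."""
    positions = {"red": (45.0, 55.0), "green": (75.0, 40.0), "blue": (110.0, 60.0)}
    angles = {"red": 30.0, "green": 0.0, "blue": -45.0}
    cubs = tuple(CuboidSpec(color=c, center_mm=positions[c], angle_deg=angles[c]) for c in colors)
    return SceneSpec(cuboids=cubs)
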