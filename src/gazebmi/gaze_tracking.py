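"""Gaze smoothing, cursor resampling and object/UI hit-testing.

Raw 60-Hz gaze samples are smoothed with a 10-point moving average
(averaging over however many samples have been seen during warm-up) and
resampled onto the 30-ms cursor cadence with a zero-order hold.  Hit
testing against segmented-object bounding boxes and GUI elements yields
the selection target the state machine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GazeFilterSpec:
    window_points: int = 10
    cursor_period_ms: float = 30.0

    def validate(self) -> None:
        if self.window_points < 1:
            raise ValueError("window_points must be >= 1")
        if self.cursor_period_ms <= 0:
            raise ValueError("cursor_period_ms must be positive")


@dataclass(frozen=True)
class UIElement:
    """A GUI hit region: the G/M circle or a coloured target area."""

    name: str  # "G_circle", "M_circle", or "target_area:<color>"
    bbox_px: tuple[float, float, float, float]  # x0, y0, x1, y1


@dataclass(frozen=True)
class Selection:
    kind: str  # "object" | "ui" | "none"
    target: object = None  # object id / UIElement name


NO_SELECTION = Selection(kind="none")


def smooth_gaze(raw: pd.DataFrame, spec: GazeFilterSpec = GazeFilterSpec()) -> pd.DataFrame:
    """Moving average of the most recent min(k, window_points) samples."""
    spec.validate()
    if len(raw) == 0:
        return raw.copy()
    out = raw.copy()
    roll = raw[["x", "y"]].rolling(spec.window_points, min_periods=1).mean()
    out[["x", "y"]] = roll
    return out


def cursor_stream(filtered: pd.DataFrame, spec: GazeFilterSpec = GazeFilterSpec()) -> pd.DataFrame:
    """Resample onto the cursor cadence with a zero-order hold.

    Cursor updates occur at t = 0, P, 2P, ... while t does not exceed the
    last filtered timestamp; each takes the latest available sample.
    """
    spec.validate()
    if len(filtered) == 0:
        raise ValueError("filtered gaze stream must be nonempty")
    t = filtered["t"].to_numpy()
    period = spec.cursor_period_ms / 1000.0
    n_updates = int(np.floor((t[-1] - t[0]) / period + 1e-9)) + 1
    ct = t[0] + np.arange(n_updates) * period
    idx = np.searchsorted(t, ct + 1e-12, side="right") - 1
    return pd.DataFrame(
        {"t": ct, "x": filtered["x"].to_numpy()[idx], "y": filtered["y"].to_numpy()[idx]}
    )


def _contains(bbox, x, y) -> bool:
    x0, y0, x1, y1 = bbox
    return x0 <= x <= x1 and y0 <= y <= y1


def hit_test(cursor_xy, objects, ui_elements: list[UIElement] = ()) -> Selection:
    """Resolve the cursor to an object, a UI element, or nothing.

    ``objects`` is a list of segmented workspace objects exposing
    ``bbox_px`` (x0, y0, x1, y1) and ``centroid_px``.  Objects take
    priority over UI elements; containment ties break toward the nearest
    centroid.  Deterministic and total.
    """
    x, y = float(cursor_xy[0]), float(cursor_xy[1])
    hits = [o for o in objects if _contains(o.bbox_px, x, y)]
    if hits:
        best = min(hits, key=lambda o: ((o.centroid_px[0] - x) ** 2 + (o.centroid_px[1] - y) ** 2,
                                        str(getattr(o, "color", ""))))
        return Selection(kind="object", target=best)
    ui_hits = [u for u in ui_elements if _contains(u.bbox_px, x, y)]
    if ui_hits:
        best = min(
            ui_hits,
            key=lambda u: (
                ((u.bbox_px[0] + u.bbox_px[2]) / 2 - x) ** 2
                + ((u.bbox_px[1] + u.bbox_px[3]) / 2 - y) ** 2,
                u.name,
            ),
        )
        return Selection(kind="ui", target=best.name)
    return NO_SELECTION
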