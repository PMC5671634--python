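"""Augmented-reality overlay geometry.

Three overlays close the visual loop during manual control: a virtual box
whose width equals the gripper aperture (grasping), two arrows whose
length is proportional to the simulated grasp force once the aperture is
below the object width, and a virtual box whose height equals the gripper
altitude, judged against the 15-mm obstacle (lifting).  All geometry is a
pure function of system state; rasterisation is an optional 2-D draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np

from .workspace_vision import CameraPose, GeometryError, project_points

#: default arrow-length gain, mm of arrow per mm of over-closure
DEFAULT_FORCE_SCALE = 1.0

#: default placement offset of the aperture box beside the object, mm
DEFAULT_APERTURE_BOX_OFFSET = (15.0, 0.0)


def is_grasped(aperture_mm: float, object_width_mm: float) -> bool:
    """The single grasp predicate shared by the AR arrows and the FSM:
    the object is held once the aperture is strictly below its width."""
    return aperture_mm < object_width_mm


@dataclass(frozen=True)
class ApertureBox:
    width_mm: float
    anchor_mm: tuple[float, float]

    def __post_init__(self):
        if self.width_mm < 0:
            raise ValueError("aperture box width must be >= 0")


@dataclass(frozen=True)
class ForceArrows:
    visible: bool
    length_mm: float
    direction: tuple[float, float] = (0.0, 1.0)  # normal to the gripper jaws


@dataclass(frozen=True)
class HeightBox:
    height_mm: float
    safe: bool


def aperture_box(gripper_state, selected_object,
                 offset_mm=DEFAULT_APERTURE_BOX_OFFSET) -> ApertureBox:
    """Box of width equal to the current aperture, anchored beside the
    selected object."""
    if selected_object is None:
        raise ValueError("no selected object for the aperture box")
    cx, cy = selected_object.center_mm if hasattr(selected_object, "center_mm") else selected_object
    return ApertureBox(
        width_mm=gripper_state.aperture_mm,
        anchor_mm=(cx + offset_mm[0], cy + offset_mm[1]),
    )


def force_arrows(object_width_mm: float, aperture_mm: float,
                 c: float = DEFAULT_FORCE_SCALE,
                 over_closure_mm: float = 0.0) -> ForceArrows:
    """Simulated grasp-force arrows: visible iff the aperture is strictly
    below the object width; length grows with the closure deficit."""
    if object_width_mm < 0 or aperture_mm < 0:
        raise ValueError("widths must be >= 0")
    visible = is_grasped(aperture_mm, object_width_mm)
    length = c * (object_width_mm - aperture_mm + over_closure_mm) if visible else 0.0
    return ForceArrows(visible=visible, length_mm=length)


def height_box(gripper_z_mm: float, table_z_mm: float = 0.0,
               obstacle_height_mm: float = 15.0) -> HeightBox:
    """Gripper-altitude box: safe iff strictly above the obstacle."""
    if gripper_z_mm < table_z_mm:
        raise ValueError("gripper below table")
    height = gripper_z_mm - table_z_mm
    return HeightBox(height_mm=height, safe=height > obstacle_height_mm)


# ---------------------------------------------------------------------------
# Rasterisation (headless 2-D draw, not a live renderer)

_OVERLAY_COLORS = {"aperture_box": (255, 255, 0), "force_arrows": (255, 0, 255),
                   "height_box": (0, 255, 255)}


def _draw_segment(img, p0, p1, color):
    from skimage.draw import line as draw_line

    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc = draw_line(r0, c0, r1, c1)
    ok = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
    img[rr[ok], cc[ok]] = color


def overlay_polyline_world(overlay, obstacle_height_mm: float = 15.0) -> np.ndarray | None:
    """World-frame (mm, z up) vertex chain of an overlay, for projection."""
    if isinstance(overlay, ApertureBox):
        x, y = overlay.anchor_mm
        w = overlay.width_mm
        return np.array([[x - w / 2, y, 0], [x + w / 2, y, 0],
                         [x + w / 2, y + 4, 0], [x - w / 2, y + 4, 0],
                         [x - w / 2, y, 0]])
    if isinstance(overlay, ForceArrows):
        if not overlay.visible:
            return None
        L = overlay.length_mm
        return np.array([[-L, 0, 0], [0, 0, 0], [0, 0, 0], [L, 0, 0]])
    if isinstance(overlay, HeightBox):
        h = overlay.height_mm
        return np.array([[0, 0, 0], [0, 0, h], [4, 0, h], [4, 0, 0], [0, 0, 0]])
    raise TypeError(f"unknown overlay {overlay!r}")


def render_overlays(scene_image: np.ndarray, overlays, pose: CameraPose,
                    obstacle_height_mm: float = 15.0) -> np.ndarray:
    """Project overlay geometry through the camera pose and draw it onto a
    copy of the scene image (the input is never modified)."""
    out = np.array(scene_image, copy=True)
    for overlay in overlays:
        verts = overlay_polyline_world(overlay, obstacle_height_mm)
        if verts is None or len(verts) < 2:
            continue
        color = _OVERLAY_COLORS.get(type(overlay).__name__.lower()) or \
            _OVERLAY_COLORS["aperture_box" if isinstance(overlay, ApertureBox)
                            else "force_arrows" if isinstance(overlay, ForceArrows)
                            else "height_box"]
        try:
            px = project_points(verts, pose)
        except GeometryError:
            warn("overlay behind camera; skipped", stacklevel=2)
            continue
        for a, b in zip(px[:-1], px[1:]):
            _draw_segment(out, a, b, color)
    return out
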