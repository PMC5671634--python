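"""Workspace vision: colour segmentation, pixel<->robot calibration, and
marker-based camera pose for AR projection.

Conventions fixed repo-wide: pixel origin top-left, x right, y down;
robot frame in millimetres, origin at workspace corner P1, x right,
y up, z up from the table.  Object angles are reported in the robot
frame, degrees in [-90, 90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label, regionprops


class GeometryError(ValueError):
    pass


def _cross2(u, v) -> float:
    """z-component of the cross product of two 2-vectors."""
    return float(u[0] * v[1] - u[1] * v[0])


# ---------------------------------------------------------------------------
# Segmentation


@dataclass(frozen=True)
class WorkspaceObject:
    """A segmented cuboid: selection and grasp target."""

    color: str
    centroid_px: tuple[float, float]
    angle_deg: float
    bbox_px: tuple[float, float, float, float]  # x0, y0, x1, y1
    width_mm: float = 10.0
    object_id: int = 0


#: generous hue bands around the pure primaries (hue in [0, 1))
DEFAULT_COLOR_THRESHOLDS = {
    "red": {"hue": (330 / 360, 30 / 360), "sat_min": 0.3, "val_min": 0.2},
    "green": {"hue": (90 / 360, 150 / 360), "sat_min": 0.3, "val_min": 0.2},
    "blue": {"hue": (210 / 360, 270 / 360), "sat_min": 0.3, "val_min": 0.2},
}

MIN_COMPONENT_AREA_PX = 50


def _hue_mask(h, band):
    lo, hi = band
    if lo <= hi:
        return (h >= lo) & (h <= hi)
    return (h >= lo) | (h <= hi)  # wrap-around (red)


def _mask_orientation_deg(mu) -> float:
    """In-plane angle of the principal axis from central image moments,
    converted to the y-up robot convention, wrapped to [-90, 90)."""
    mu_xx, mu_yy, mu_xy = mu[0, 2], mu[2, 0], -mu[1, 1]
    angle = 0.5 * np.degrees(np.arctan2(2 * mu_xy, mu_xx - mu_yy))
    return ((angle + 90.0) % 180.0) - 90.0


def segment_cuboids(
    image: np.ndarray,
    color_thresholds: dict | None = None,
    min_area_px: int = MIN_COMPONENT_AREA_PX,
    width_mm: float = 10.0,
) -> list[WorkspaceObject]:
    """Segment coloured cuboids from an RGB workspace image.

    RGB -> HSV (robust to illumination), per-colour hue/saturation/value
    threshold masks, connected components above ``min_area_px``; each
    component yields a centroid (mask mean), principal-axis angle and
    axis-aligned bounding box.
    """
    thresholds = color_thresholds or DEFAULT_COLOR_THRESHOLDS
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img / 255.0
    hsv = rgb2hsv(img)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]

    objects: list[WorkspaceObject] = []
    oid = 0
    for color, th in thresholds.items():
        mask = _hue_mask(h, th["hue"]) & (s >= th["sat_min"]) & (v >= th["val_min"])
        labelled = cc_label(mask)
        for region in regionprops(labelled):
            if region.area < min_area_px:
                continue
            r0, c0, r1, c1 = region.bbox
            cy, cx = region.centroid
            objects.append(
                WorkspaceObject(
                    color=color,
                    centroid_px=(cx, cy),
                    angle_deg=_mask_orientation_deg(region.moments_central),
                    bbox_px=(c0, r0, c1 - 1, r1 - 1),
                    width_mm=width_mm,
                    object_id=oid,
                )
            )
            oid += 1
    return objects


# ---------------------------------------------------------------------------
# Homography (pixel <-> robot plane)


@dataclass(frozen=True)
class CalibrationCorrespondence:
    pixel_corners: np.ndarray  # 4 x 2, p1..p4
    robot_corners: np.ndarray  # 4 x 2, P1..P4

    def validate(self) -> None:
        for pts, name in ((np.asarray(self.pixel_corners), "pixel"),
                          (np.asarray(self.robot_corners), "robot")):
            if pts.shape != (4, 2):
                raise GeometryError(f"{name}_corners must be 4 x 2")
            for i in range(4):
                a, b, c = np.delete(pts, i, axis=0)
                if abs(_cross2(b - a, c - a)) < 1e-9:
                    raise GeometryError(f"degenerate {name} quadrilateral (collinear points)")


@dataclass(frozen=True)
class Homography:
    """3x3 projective map, normalised so H[2, 2] = 1."""

    matrix: np.ndarray

    def __post_init__(self):
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise GeometryError("homography matrix is singular")

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack((p, np.ones(len(p)))) @ self.matrix.T
        w = hom[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise GeometryError("point maps to infinity (zero homogeneous coordinate)")
        out = hom[:, :2] / w[:, None]
        return out if np.ndim(points) > 1 else out[0]

    def inverse(self) -> "Homography":
        m = np.linalg.inv(self.matrix)
        return Homography(matrix=m / m[2, 2])


def _dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Exact 4-point direct linear transform: 8 equations, 8 unknowns."""
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i] = u
        b[2 * i + 1] = v
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise GeometryError("degenerate correspondence for homography") from exc
    return np.append(h, 1.0).reshape(3, 3)


def calibrate_homography(corr: CalibrationCorrespondence) -> Homography:
    """Pixel -> robot perspective transform from the 4 workspace corners
    (p1..p4 <-> P1..P4); exact on its defining correspondences."""
    corr.validate()
    m = _dlt_homography(np.asarray(corr.pixel_corners, float),
                        np.asarray(corr.robot_corners, float))
    return Homography(matrix=m)


def pixel_to_robot(point_px, h: Homography) -> np.ndarray:
    return h.apply(point_px)


def robot_to_pixel(point_mm, h: Homography) -> np.ndarray:
    return h.inverse().apply(point_mm)


# ---------------------------------------------------------------------------
# Camera pose from the planar marker


@dataclass(frozen=True)
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0, self.cx], [0, self.fy, self.cy], [0, 0, 1.0]])


@dataclass(frozen=True)
class MarkerSpec:
    """Square AR marker centred at the world origin (0, 0, 0)."""

    width_mm: float = 1.0

    def corners_world(self) -> np.ndarray:
        s = self.width_mm / 2.0
        return np.array([[-s, -s, 0], [s, -s, 0], [s, s, 0], [-s, s, 0]], dtype=float)


@dataclass(frozen=True)
class CameraPose:
    """World -> camera rigid transform plus intrinsics.

    X_cam = rotation @ X_world + translation; projection is an ideal
    pinhole (no distortion in simulation).
    """

    rotation: np.ndarray
    translation: np.ndarray
    intrinsics: CameraIntrinsics

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise GeometryError("rotation must be orthonormal with determinant +1")


def project_points(points_world_mm, pose: CameraPose) -> np.ndarray:
    """Pinhole projection of world points; raises if a point is at or
    behind the camera plane."""
    p = np.atleast_2d(np.asarray(points_world_mm, dtype=float))
    cam = p @ pose.rotation.T + pose.translation
    if np.any(cam[:, 2] <= 1e-9):
        raise GeometryError("point at or behind the camera plane")
    k = pose.intrinsics
    out = np.column_stack(
        (k.fx * cam[:, 0] / cam[:, 2] + k.cx, k.fy * cam[:, 1] / cam[:, 2] + k.cy)
    )
    return out if np.ndim(points_world_mm) > 1 else out[0]


def estimate_pose(
    marker_corners_px, marker: MarkerSpec, intrinsics: CameraIntrinsics
) -> CameraPose:
    """Planar PnP by homography decomposition.

    The marker lies in the z = 0 world plane, so the world->pixel map is a
    homography H = K [r1 r2 t] up to scale; the pose follows from the DLT
    homography of the 4 ordered corners, with the rotation orthonormalised
    by SVD (nearest rotation matrix).
    """
    px = np.asarray(marker_corners_px, dtype=float)
    if px.shape != (4, 2):
        raise GeometryError("need 4 ordered marker corners")
    world = marker.corners_world()[:, :2]
    for i in range(4):
        a, b, c = np.delete(px, i, axis=0)
        if abs(_cross2(b - a, c - a)) < 1e-9:
            raise GeometryError("collinear marker corners")
    H = _dlt_homography(world, px)
    M = np.linalg.inv(intrinsics.K) @ H
    l1, l2 = np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1])
    lam = 2.0 / (l1 + l2)
    r1, r2, t = lam * M[:, 0], lam * M[:, 1], lam * M[:, 2]
    if t[2] < 0:  # camera must see the marker in front of it
        r1, r2, t = -r1, -r2, -t
    R_approx = np.column_stack((r1, r2, np.cross(r1, r2)))
    U, _, Vt = np.linalg.svd(R_approx)
    R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    return CameraPose(rotation=R, translation=t, intrinsics=intrinsics)
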