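"""Calibrated pinhole stereo geometry: projection, triangulation, refinement.

The world frame is right-handed, in millimeters, with its origin at the
perch (the resting position of the hand).  Cameras follow the standard
computer-vision convention: a point ``p`` in world coordinates maps to
camera coordinates ``R @ p + t``, the camera looks along its +z axis, and
pixel coordinates have the origin at the top-left corner, x rightward and
y downward.  Lens distortion is radial with two coefficients, applied to
normalized image coordinates before the intrinsics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


class DegenerateGeometryError(ValueError):
    """Raised when rays are (near-)parallel and triangulation is undefined."""


@dataclass
class CameraModel:
    """Pinhole camera with two-term radial distortion.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    cx, cy : float
        Principal point in pixels.
    k1, k2 : float
        Radial distortion coefficients (dimensionless).
    rotation : (3, 3) ndarray
        World-to-camera rotation; must be orthonormal.
    translation : (3,) ndarray
        World-to-camera translation in mm.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates (mm)."""
        return -self.rotation.T @ self.translation

    @property
    def optical_axis(self) -> np.ndarray:
        """Unit viewing direction (camera +z) in world coordinates."""
        return self.rotation.T @ np.array([0.0, 0.0, 1.0])

    def to_dict(self) -> dict:
        return {
            "fx": float(self.fx), "fy": float(self.fy),
            "cx": float(self.cx), "cy": float(self.cy),
            "distortion": {"k1": float(self.k1), "k2": float(self.k2)},
            "rotation": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
            k1=d["distortion"]["k1"], k2=d["distortion"]["k2"],
            rotation=np.asarray(d["rotation"]),
            translation=np.asarray(d["translation_mm"]),
        )


@dataclass
class StereoRig:
    """Pair of calibrated cameras (front and side views)."""

    front: CameraModel
    side: CameraModel

    def __post_init__(self) -> None:
        cosang = float(np.clip(self.front.optical_axis @ self.side.optical_axis, -1, 1))
        if np.degrees(np.arccos(abs(cosang))) < 1.0:
            raise ValueError("optical axes are within 1 degree of parallel")

    def to_yaml(self, path) -> None:
        doc = {
            "units": {"length": "mm", "pixels": "px"},
            "world_frame": "right-handed, origin at perch",
            "front": self.front.to_dict(),
            "side": self.side.to_dict(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StereoRig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(front=CameraModel.from_dict(doc["front"]),
                   side=CameraModel.from_dict(doc["side"]))


def default_rig(working_distance_mm: float = 200.0,
                focal_px: float = 800.0,
                image_size: tuple[int, int] = (352, 260)) -> StereoRig:
    """Two perpendicular cameras at the given working distance from the perch.

    The front camera looks along world +z, the side camera along world -x,
    matching the perpendicular front/side arrangement of the recording setup.
    """
    cx, cy = image_size[0] / 2.0, image_size[1] / 2.0
    front = CameraModel(fx=focal_px, fy=focal_px, cx=cx, cy=cy,
                        rotation=np.eye(3),
                        translation=np.array([0.0, 0.0, working_distance_mm]))
    # side camera sits on world +x; rotation about y by +90 deg maps +x to -z
    ry = Rotation.from_euler("y", 90, degrees=True).as_matrix()
    side = CameraModel(fx=focal_px, fy=focal_px, cx=cx, cy=cy,
                       rotation=ry,
                       translation=np.array([0.0, 0.0, working_distance_mm]))
    return StereoRig(front=front, side=side)


def project_point(p, cam: CameraModel):
    """Project world point(s) in mm to pixel coordinates.

    Accepts a single 3-vector or an (N, 3) array; returns a matching
    2-vector or (N, 2) array.  Raises ``ValueError`` for points at or
    behind the camera plane.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    cam_pts = pts @ cam.rotation.T + cam.translation
    z = cam_pts[:, 2]
    if np.any(z <= 0):
        raise ValueError("point has non-positive depth in camera frame")
    xn = cam_pts[:, 0] / z
    yn = cam_pts[:, 1] / z
    r2 = xn * xn + yn * yn
    d = 1.0 + cam.k1 * r2 + cam.k2 * r2 * r2
    u = cam.fx * xn * d + cam.cx
    v = cam.fy * yn * d + cam.cy
    uv = np.column_stack([u, v])
    return uv[0] if single else uv


def undistort_normalized(xd, yd, k1: float, k2: float, n_iter: int = 20):
    """Invert the radial distortion model by fixed-point iteration."""
    xu, yu = np.asarray(xd, float), np.asarray(yd, float)
    for _ in range(n_iter):
        r2 = xu * xu + yu * yu
        d = 1.0 + k1 * r2 + k2 * r2 * r2
        xu = xd / d
        yu = yd / d
    return xu, yu


def _ray(obs, cam: CameraModel):
    """World-frame origin and unit direction of the back-projected ray."""
    xd = (obs[0] - cam.cx) / cam.fx
    yd = (obs[1] - cam.cy) / cam.fy
    xu, yu = undistort_normalized(xd, yd, cam.k1, cam.k2)
    direction = cam.rotation.T @ np.array([float(xu), float(yu), 1.0])
    direction /= np.linalg.norm(direction)
    return cam.center, direction


def triangulate(obs_front, obs_side, rig: StereoRig,
                refine: bool = True,
                condition_threshold: float = 1e6) -> tuple[np.ndarray, float]:
    """Intersect the two back-projected rays and report the residual.

    Solves the linear least-squares ray intersection (the point minimizing
    summed squared perpendicular distance to both rays), then optionally
    refines by minimizing the summed squared pixel reprojection error.

    Returns
    -------
    point : (3,) ndarray in mm
    residual : float
        Root-mean-square reprojection error over the four pixel residuals.
    """
    obs_front = np.asarray(obs_front, float)
    obs_side = np.asarray(obs_side, float)
    if not (np.all(np.isfinite(obs_front)) and np.all(np.isfinite(obs_side))):
        raise ValueError("observations must be finite")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for obs, cam in ((obs_front, rig.front), (obs_side, rig.side)):
        c, d = _ray(obs, cam)
        P = np.eye(3) - np.outer(d, d)
        A += P
        b += P @ c
    if np.linalg.cond(A) > condition_threshold:
        raise DegenerateGeometryError("rays are near-parallel; cannot triangulate")
    point = np.linalg.solve(A, b)

    def residuals(p):
        return np.concatenate([
            project_point(p, rig.front) - obs_front,
            project_point(p, rig.side) - obs_side,
        ])

    if refine:
        try:
            sol = least_squares(residuals, point, method="lm", xtol=1e-12, ftol=1e-12)
            point = sol.x
            res = sol.fun
        except ValueError:
            res = residuals(point)
    else:
        res = residuals(point)
    return point, float(np.sqrt(np.mean(res ** 2)))


def triangulate_track(track_front, track_side, rig: StereoRig,
                      refine: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate paired 2D tracks frame-by-frame.

    Returns (N, 3) points in mm and (N,) RMS reprojection residuals in px.
    Frames with non-finite observations yield NaN rows.
    """
    track_front = np.asarray(track_front, float)
    track_side = np.asarray(track_side, float)
    if track_front.shape != track_side.shape:
        raise ValueError("front and side tracks must have equal shape")
    n = track_front.shape[0]
    pts = np.full((n, 3), np.nan)
    res = np.full(n, np.nan)
    for i in range(n):
        if not (np.all(np.isfinite(track_front[i])) and np.all(np.isfinite(track_side[i]))):
            continue
        pts[i], res[i] = triangulate(track_front[i], track_side[i], rig, refine=refine)
    return pts, res


def reprojection_error(rig: StereoRig, track_front, track_side) -> float:
    """Mean RMS reprojection error of triangulated correspondences, in px."""
    _, res = triangulate_track(track_front, track_side, rig, refine=True)
    return float(np.nanmean(res))


def refine_calibration(rig: StereoRig, track_front, track_side,
                       adjust_intrinsics: bool = False,
                       min_correspondences: int = 20) -> StereoRig:
    """Fine-tune the rig against a set of 2D track correspondences.

    The front camera anchors the world frame; only the side camera's
    extrinsics (and, optionally, both cameras' focal lengths and principal
    points) are adjusted to minimize the total reprojection error of the
    triangulated correspondences.  The refined rig never has a larger mean
    reprojection error than the input rig.
    """
    track_front = np.asarray(track_front, float)
    track_side = np.asarray(track_side, float)
    ok = np.all(np.isfinite(track_front), axis=1) & np.all(np.isfinite(track_side), axis=1)
    track_front, track_side = track_front[ok], track_side[ok]
    if len(track_front) < min_correspondences:
        raise ValueError(
            f"need at least {min_correspondences} correspondences, got {len(track_front)}")
    pts0, _ = triangulate_track(track_front, track_side, rig, refine=False)
    sv = np.linalg.svd(pts0 - pts0.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError("correspondences are collinear; refinement is ill-posed")

    rotvec0 = Rotation.from_matrix(rig.side.rotation).as_rotvec()
    x0 = np.concatenate([rotvec0, rig.side.translation])
    if adjust_intrinsics:
        x0 = np.concatenate([x0, [rig.front.fx, rig.front.fy, rig.front.cx, rig.front.cy,
                                  rig.side.fx, rig.side.fy, rig.side.cx, rig.side.cy]])

    def build(x) -> StereoRig:
        side = CameraModel(
            fx=x[10] if adjust_intrinsics else rig.side.fx,
            fy=x[11] if adjust_intrinsics else rig.side.fy,
            cx=x[12] if adjust_intrinsics else rig.side.cx,
            cy=x[13] if adjust_intrinsics else rig.side.cy,
            k1=rig.side.k1, k2=rig.side.k2,
            rotation=Rotation.from_rotvec(x[:3]).as_matrix(),
            translation=x[3:6],
        )
        front = rig.front
        if adjust_intrinsics:
            front = CameraModel(fx=x[6], fy=x[7], cx=x[8], cy=x[9],
                                k1=rig.front.k1, k2=rig.front.k2,
                                rotation=rig.front.rotation,
                                translation=rig.front.translation)
        return StereoRig(front=front, side=side)

    def cost(x):
        candidate = build(x)
        out = []
        for f, s in zip(track_front, track_side):
            try:
                p, _ = triangulate(f, s, candidate, refine=False)
                out.append(np.concatenate([
                    project_point(p, candidate.front) - f,
                    project_point(p, candidate.side) - s,
                ]))
            except (DegenerateGeometryError, ValueError):
                out.append(np.full(4, 1e3))
        return np.concatenate(out)

    sol = least_squares(cost, x0, method="trf", xtol=1e-12, ftol=1e-12)
    refined = build(sol.x)
    before = reprojection_error(rig, track_front, track_side)
    after = reprojection_error(refined, track_front, track_side)
    if after > before + 1e-9:
        warnings.warn("refinement did not improve reprojection error; keeping input rig")
        return rig
    return refined
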