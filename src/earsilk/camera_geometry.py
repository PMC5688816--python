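"""Pinhole + turntable camera model: calibration and pixel <-> world mapping.

The plant rotates on a turntable about a vertical axis while a fixed camera
takes side views every 30 degrees.  A world point p (mm, turntable frame,
z up, origin at the pot top on the rotation axis) observed at turntable angle
theta projects as

    pixel = K [R | t] Rz(theta, axis) p

with K the intrinsic matrix (zero skew) and (R, t) the camera pose.  The
single-view depth ambiguity when inverting this map is closed by intersecting
the back-projected ray with the vertical plane through the rotation axis at
the plant's leaf-plane azimuth — the plane the platform turns perpendicular
to the camera before close-up imaging.

Calibration fits all parameters to chessboard corner observations taken at
known turntable angles by least squares on the reprojection error.  The
turntable axis is fixed at the world origin: letting it float is a gauge
freedom (an axis shift is absorbed exactly by board and camera translations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


class ProjectionError(ValueError):
    """Point behind the camera or otherwise unprojectable."""


@dataclass
class CameraModel:
    fx: float
    fy: float
    cx: float
    cy: float
    rotation: np.ndarray           # (3,3) camera-from-world
    translation: np.ndarray        # (3,) mm
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(2))  # axis x,y

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6) or \
                not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must be orthonormal with determinant 1")

    @property
    def intrinsics(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]])

    def to_json(self, path: str | Path) -> None:
        data = {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
                "rotation": self.rotation.tolist(), "translation": self.translation.tolist(),
                "axis_point": self.axis_point.tolist()}
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraModel":
        d = json.loads(Path(path).read_text())
        return cls(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                   rotation=np.array(d["rotation"]), translation=np.array(d["translation"]),
                   axis_point=np.array(d.get("axis_point", [0.0, 0.0])))


@dataclass
class ChessboardSpec:
    """Planar corner grid rigidly mounted on the turntable."""

    n_cols: int = 7
    n_rows: int = 5
    square_size: float = 20.0      # mm
    rotvec: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def corner_board_points(self) -> np.ndarray:
        ii, jj = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        pts = np.stack([ii.ravel() * self.square_size, jj.ravel() * self.square_size,
                        np.zeros(self.n_cols * self.n_rows)], axis=1)
        return pts

    def corner_world_points(self) -> np.ndarray:
        R = Rotation.from_rotvec(np.asarray(self.rotvec, dtype=float)).as_matrix()
        return self.corner_board_points() @ R.T + np.asarray(self.translation, dtype=float)


def _rotate_about_axis(points: np.ndarray, angle_deg: float, axis_xy: np.ndarray) -> np.ndarray:
    """Rotate points about the vertical line through (axis_x, axis_y)."""
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    pivot = np.array([axis_xy[0], axis_xy[1], 0.0])
    pts = np.atleast_2d(points) - pivot
    return pts @ Rz.T + pivot


def project(model: CameraModel, world_point, turntable_angle: float = 0.0) -> np.ndarray:
    """World point (turntable frame) at given table angle -> sub-pixel (u, v)."""
    p = _rotate_about_axis(np.asarray(world_point, dtype=float), turntable_angle,
                           model.axis_point)[0]
    cam = model.rotation @ p + model.translation
    if cam[2] <= 1e-9:
        raise ProjectionError(f"point {world_point} behind camera (z={cam[2]:.3g})")
    return np.array([model.fx * cam[0] / cam[2] + model.cx,
                     model.fy * cam[1] / cam[2] + model.cy])


def back_project_ray(model: CameraModel, pixel) -> tuple[np.ndarray, np.ndarray]:
    """Camera-frame pixel -> (origin, direction) of the viewing ray in world frame."""
    u, v = float(pixel[0]), float(pixel[1])
    d_cam = np.array([(u - model.cx) / model.fx, (v - model.cy) / model.fy, 1.0])
    Rt = model.rotation.T
    origin = -Rt @ model.translation
    direction = Rt @ d_cam
    return origin, direction


def pixel_to_world(model: CameraModel, pixel, view_azimuth: float,
                   plant_plane_azimuth: float) -> np.ndarray:
    """Ear pixel in a side view -> [x, y, z] mm in the (unrotated) plant frame.

    The ray is intersected with the vertical plane through the turntable axis
    whose in-plane direction has azimuth ``plant_plane_azimuth`` in the plant
    frame (hence ``plant_plane_azimuth + view_azimuth`` in the world frame at
    imaging time); the intersection is then rotated back by -view_azimuth.
    """
    origin, direction = back_project_ray(model, pixel)
    alpha = np.radians(plant_plane_azimuth + view_azimuth)
    normal = np.array([-np.sin(alpha), np.cos(alpha), 0.0])
    anchor = np.array([model.axis_point[0], model.axis_point[1], 0.0])
    denom = normal @ direction
    if abs(denom) < 1e-12:
        raise ProjectionError("viewing ray parallel to the plant plane")
    s = normal @ (anchor - origin) / denom
    q = origin + s * direction
    return _rotate_about_axis(q, -view_azimuth, model.axis_point)[0]


# ---------------------------------------------------------------------------
# calibration


def reprojection_residuals(model: CameraModel, board: ChessboardSpec, observations):
    res = []
    for angle, corners in observations:
        world = board.corner_world_points()
        for p, obs in zip(world, np.asarray(corners, dtype=float)):
            res.append(project(model, p, angle) - obs)
    return np.concatenate(res)


def reprojection_rms(model: CameraModel, board: ChessboardSpec, observations) -> float:
    r = reprojection_residuals(model, board, observations).reshape(-1, 2)
    return float(np.sqrt(np.mean(np.sum(r**2, axis=1))))


def _pack(model: CameraModel, board: ChessboardSpec) -> np.ndarray:
    rv = Rotation.from_matrix(model.rotation).as_rotvec()
    return np.concatenate([[model.fx, model.fy, model.cx, model.cy], rv, model.translation,
                           board.rotvec, board.translation])


def _unpack(params: np.ndarray, board: ChessboardSpec):
    fx, fy, cx, cy = params[:4]
    R = Rotation.from_rotvec(params[4:7]).as_matrix()
    t = params[7:10]
    b = ChessboardSpec(n_cols=board.n_cols, n_rows=board.n_rows,
                       square_size=board.square_size,
                       rotvec=params[10:13].copy(), translation=params[13:16].copy())
    model = CameraModel(fx=fx, fy=fy, cx=cx, cy=cy, rotation=R, translation=t)
    return model, b


def calibrate(corner_observations, board_geometry: ChessboardSpec,
              initial_guess: CameraModel, max_rms: float = 50.0):
    """Fit intrinsics, camera pose and board pose to corner observations.

    ``corner_observations`` is a list of (turntable_angle_deg, (N,2) pixel
    array).  Returns (CameraModel, board pose, final RMS reprojection error
    in px).  Raises on fewer than 3 poses, fewer than 6 corners per pose, or
    non-convergence (final RMS above ``max_rms``).
    """
    if len(corner_observations) < 3:
        raise ValueError("need at least 3 board poses")
    for _, corners in corner_observations:
        if len(np.atleast_2d(corners)) < 6:
            raise ValueError("need at least 6 corners per pose")
    x0 = _pack(initial_guess, board_geometry)

    def fun(params):
        model, b = _unpack(params, board_geometry)
        try:
            return reprojection_residuals(model, b, corner_observations)
        except ProjectionError:
            return np.full(2 * sum(len(np.atleast_2d(c)) for _, c in corner_observations), 1e6)

    sol = least_squares(fun, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    model, fitted_board = _unpack(sol.x, board_geometry)
    rms = reprojection_rms(model, fitted_board, corner_observations)
    if not sol.success or not np.isfinite(rms) or rms > max_rms:
        raise RuntimeError(f"calibration did not converge (RMS {rms:.3g} px)")
    return model, fitted_board, rms
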