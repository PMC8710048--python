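"""Calibrated pinhole cameras for turntable plant imaging.

The imaging geometry modeled here is a plant on a rotating turntable
photographed by one fixed side camera (the table is rotated to the
requested angle between exposures) plus one overhead camera.  The world
frame is right-handed with ``z`` up; the turntable axis is the world
``z`` axis, and the reconstruction volume is a cube of side ``L``
spanning ``x, y in [-L/2, L/2]`` and ``z in [0, L]`` (soil surface at
``z = 0``).

A side view at turntable angle ``alpha`` is implemented by rotating the
world about the ``z`` axis by ``-alpha`` and projecting through a pinhole
camera placed at distance ``camera_distance`` from the axis, at half the
volume height, looking horizontally at the axis.  ``axis_offset``
expresses the calibration fact that the pot center need not sit exactly
on the rotation axis: plant coordinates are displaced by this 2D offset
before the turntable rotation is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

SIDE_VIEW_ANGLES = (0.0, 72.0, 144.0, 216.0, 288.0)

DEFAULT_VOLUME_SIDE_MM = 600.0


@dataclass(frozen=True)
class CameraModel:
    """A calibrated perspective view of the turntable volume.

    Parameters
    ----------
    view_kind : {"side", "top"}
        Side cameras look horizontally at the turntable axis; the top
        camera looks straight down the axis.
    turntable_angle : float
        Turntable rotation in degrees when the exposure was taken.
    focal_length : float
        Focal length in pixels (square pixels assumed).
    principal_point : tuple of float
        Image coordinates ``(cx, cy)`` of the optical center, pixels.
    camera_distance : float
        Side views: horizontal distance from the rotation axis to the
        pinhole, mm.  Top view: height of the pinhole above the soil
        plane (world ``z = 0``), mm.
    axis_offset : tuple of float
        2D displacement ``(ox, oy)`` in mm of the pot center from the
        rotation axis, applied to world points before the turntable
        rotation (the calibration correction for off-axis pots).
    image_size : tuple of int
        ``(width, height)`` in pixels.
    volume_side : float
        Side length of the cubic reconstruction volume, mm.  Used only
        to place the side camera's optical axis at half volume height.
    """

    view_kind: str = "side"
    turntable_angle: float = 0.0
    focal_length: float = 2400.0
    principal_point: tuple[float, float] = (320.0, 320.0)
    camera_distance: float = 3000.0
    axis_offset: tuple[float, float] = (0.0, 0.0)
    image_size: tuple[int, int] = (640, 640)
    volume_side: float = DEFAULT_VOLUME_SIDE_MM

    def __post_init__(self) -> None:
        if self.view_kind not in ("side", "top"):
            raise ValueError(f"view_kind must be 'side' or 'top', got {self.view_kind!r}")
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    def _camera_frame(self, points: np.ndarray) -> np.ndarray:
        """Map world points (N, 3) to camera coordinates (X right, Y down,
        Z depth along the optical axis)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        ox, oy = self.axis_offset
        q = pts + np.array([ox, oy, 0.0])
        a = np.deg2rad(self.turntable_angle)
        if a != 0.0:
            c, s = np.cos(-a), np.sin(-a)
            q = q @ np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
        out = np.empty_like(q)
        if self.view_kind == "side":
            h = self.volume_side / 2.0
            out[:, 0] = q[:, 0]
            out[:, 1] = h - q[:, 2]
            out[:, 2] = q[:, 1] + self.camera_distance
        else:  # top, looking straight down
            out[:, 0] = q[:, 0]
            out[:, 1] = q[:, 1]
            out[:, 2] = self.camera_distance - q[:, 2]
        return out

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points to pixel coordinates.

        Returns ``(uv, depth)`` where ``uv`` is (N, 2) float pixel
        coordinates and ``depth`` the distance along the optical axis
        (mm); points with non-positive depth project behind the camera
        and get ``uv = nan``.
        """
        cam = self._camera_frame(points)
        depth = cam[:, 2]
        cx, cy = self.principal_point
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.focal_length * cam[:, 0] / depth + cx
            v = self.focal_length * cam[:, 1] / depth + cy
        uv = np.stack([u, v], axis=1)
        uv[depth <= 0] = np.nan
        return uv, depth

    def in_image(self, uv: np.ndarray) -> np.ndarray:
        """Boolean mask of projections falling inside the image bounds."""
        w, hgt = self.image_size
        uv = np.asarray(uv, dtype=float).reshape(-1, 2)
        ok = np.isfinite(uv).all(axis=1)
        ok &= (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < hgt)
        return ok

    def pixel_rays(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World-frame viewing rays for pixel coordinates.

        Returns ``(origin, directions)``: a single (3,) ray origin (the
        pinhole) and unit direction vectors with the same leading shape
        as ``u``.  Inverse of :meth:`project` up to scale; used for
        analytic silhouettes of simple solids.
        """
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        cx, cy = self.principal_point
        d_cam = np.stack(
            [(u - cx) / self.focal_length, (v - cy) / self.focal_length, np.ones_like(u)],
            axis=-1,
        )
        # camera frame -> turntable frame
        if self.view_kind == "side":
            h = self.volume_side / 2.0
            origin_t = np.array([0.0, -self.camera_distance, h])
            m = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
        else:
            origin_t = np.array([0.0, 0.0, self.camera_distance])
            m = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, -1.0]])
        d_t = d_cam @ m.T
        a = np.deg2rad(self.turntable_angle)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        ox, oy = self.axis_offset
        shift = np.array([ox, oy, 0.0])
        origin = rot @ origin_t - shift
        d_w = d_t @ rot.T
        d_w /= np.linalg.norm(d_w, axis=-1, keepdims=True)
        return origin, d_w

    # ------------------------------------------------------------------
    # (de)serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["principal_point"] = list(self.principal_point)
        d["axis_offset"] = list(self.axis_offset)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        d = dict(d)
        for key in ("principal_point", "axis_offset"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        if "image_size" in d:
            d["image_size"] = tuple(int(x) for x in d["image_size"])
        return cls(**d)


def default_rig(
    image_size: tuple[int, int] = (640, 640),
    focal_length: float = 2400.0,
    camera_distance: float = 3000.0,
    top_distance: float = 3500.0,
    axis_offset: tuple[float, float] = (0.0, 0.0),
    volume_side: float = DEFAULT_VOLUME_SIDE_MM,
) -> list[CameraModel]:
    """The six-view rig: five side views at 72-degree turntable steps
    (0, 72, 144, 216, 288) plus one overhead view."""
    cx = image_size[0] / 2.0
    cy = image_size[1] / 2.0
    views = [
        CameraModel(
            view_kind="side",
            turntable_angle=a,
            focal_length=focal_length,
            principal_point=(cx, cy),
            camera_distance=camera_distance,
            axis_offset=axis_offset,
            image_size=image_size,
            volume_side=volume_side,
        )
        for a in SIDE_VIEW_ANGLES
    ]
    views.append(
        CameraModel(
            view_kind="top",
            turntable_angle=0.0,
            focal_length=focal_length,
            principal_point=(cx, cy),
            camera_distance=top_distance,
            axis_offset=axis_offset,
            image_size=image_size,
            volume_side=volume_side,
        )
    )
    return views


def save_cameras(cameras: list[CameraModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in cameras], indent=2))


def load_cameras(path: str | Path) -> list[CameraModel]:
    return [CameraModel.from_dict(d) for d in json.loads(Path(path).read_text())]
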