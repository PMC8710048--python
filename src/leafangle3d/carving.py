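"""Voxel carving (visual hull) reconstruction and reprojection QC.

The reconstruction volume is an axis-aligned cube discretized into
``R^3`` voxels.  Carving keeps a voxel iff its center projects to a
foreground pixel in every view in which it projects inside the image —
the discrete visual hull, a guaranteed superset of the photographed
solid.  Reprojecting the hull back into a view and scoring its overlap
with the original silhouette (Jaccard index here) is the quality-control
step: reconstructions whose concordance falls below 0.8 in any view are
flagged as failures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cameras import CameraModel, DEFAULT_VOLUME_SIDE_MM

# QC failure taxonomy
REASON_NO_PLANT = "no-plant"
REASON_CALIBRATION = "calibration-failure"
REASON_LOW_CONCORDANCE = "low-concordance"
REASON_NO_STEM_JUNCTION = "no-stem-junction"


@dataclass
class VoxelGrid:
    """Cubic occupancy grid.

    ``occupancy[ix, iy, iz]`` covers the world-space cube with
    ``x, y in [-side/2, side/2]`` and ``z in [0, side]``; voxel centers
    are at ``origin + (index + 0.5) * voxel_size``.
    """

    resolution: int
    side: float = DEFAULT_VOLUME_SIDE_MM
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if self.occupancy is None:
            self.occupancy = np.zeros((self.resolution,) * 3, dtype=bool)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != (self.resolution,) * 3:
            raise ValueError("occupancy shape does not match resolution")

    @property
    def voxel_size(self) -> float:
        return self.side / self.resolution

    @property
    def origin(self) -> np.ndarray:
        return np.array([-self.side / 2.0, -self.side / 2.0, 0.0])

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (N, 3) -> world coordinates of voxel centers."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """World points (N, 3) -> containing voxel indices (may be out of range)."""
        return np.floor((np.asarray(pts, dtype=float) - self.origin) / self.voxel_size).astype(int)

    def occupied_indices(self) -> np.ndarray:
        return np.argwhere(self.occupancy)

    def occupied_centers(self) -> np.ndarray:
        return self.index_to_world(self.occupied_indices())

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Header line (JSON) + packed-bit occupancy payload."""
        header = json.dumps({"resolution": self.resolution, "side": self.side})
        with open(path, "wb") as fh:
            fh.write(header.encode() + b"\n")
            fh.write(np.packbits(self.occupancy.ravel()).tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "VoxelGrid":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            bits = np.frombuffer(fh.read(), dtype=np.uint8)
        r = int(header["resolution"])
        occ = np.unpackbits(bits, count=r**3).astype(bool).reshape((r,) * 3)
        return cls(resolution=r, side=float(header["side"]), occupancy=occ)

    def export_xyz(self, path: str | Path) -> None:
        """ASCII x y z list (mm) of occupied voxel centers, for viewers."""
        np.savetxt(path, self.occupied_centers(), fmt="%.3f")


def carve(
    masks: list[np.ndarray],
    cameras: list[CameraModel],
    resolution: int = 512,
    side: float = DEFAULT_VOLUME_SIDE_MM,
    chunk_voxels: int = 2_000_000,
) -> VoxelGrid:
    """Carve the visual hull from per-view silhouettes.

    A voxel survives iff its center projects to a foreground pixel in
    every view in which it projects inside the image.  An all-background
    view empties the grid (warned, since it usually means no plant was
    present).
    """
    if len(masks) != len(cameras):
        raise ValueError(f"{len(masks)} masks but {len(cameras)} cameras")
    if not masks:
        raise ValueError("need at least one view")
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    empty_view = False
    for mask, cam in zip(masks, cameras):
        w, h = cam.image_size
        if mask.shape != (h, w):
            raise ValueError("mask dimensions must match camera image size")
        if not mask.any():
            warnings.warn("a view is entirely background; carved grid will be empty")
            empty_view = True

    grid = VoxelGrid(resolution=resolution, side=side)
    if empty_view:
        # no plant visible in at least one view: nothing to reconstruct
        return grid
    r = resolution
    flat_alive = np.ones(r**3, dtype=bool)
    for start in range(0, r**3, chunk_voxels):
        sl = slice(start, min(start + chunk_voxels, r**3))
        flat = np.arange(sl.start, sl.stop)
        idx = np.stack([flat // (r * r), (flat // r) % r, flat % r], axis=1)
        centers = grid.index_to_world(idx)
        alive = np.ones(sl.stop - sl.start, dtype=bool)
        for mask, cam in zip(masks, cameras):
            if not alive.any():
                break
            uv, _ = cam.project(centers)
            inside = cam.in_image(uv)
            px = np.zeros_like(alive)
            u = uv[inside, 0].astype(int)
            v = uv[inside, 1].astype(int)
            px[inside] = mask[v, u]
            # kill voxels that project inside this view onto background
            alive &= ~(inside & ~px)
        flat_alive[sl] = alive
    grid.occupancy = flat_alive.reshape((r, r, r))
    return grid


def reproject(grid: VoxelGrid, camera: CameraModel, footprint: int | None = None) -> np.ndarray:
    """Render the occupancy back into a view: a pixel is foreground iff
    at least one occupied voxel projects onto it.

    Each voxel is splatted as a square pixel block to avoid aliasing
    holes.  By default the block edge matches the voxel's projected
    size (at least 2 px, so coarse grids reproject without gaps); pass
    ``footprint`` to force a fixed block edge (2 is appropriate at the
    512^3 working resolution where a voxel covers about one pixel).
    """
    w, h = camera.image_size
    mask = np.zeros((h, w), dtype=bool)
    centers = grid.occupied_centers()
    if len(centers) == 0:
        return mask
    uv, depth = camera.project(centers)
    ok = depth > 0
    if footprint is None:
        px = camera.focal_length * grid.voxel_size / np.maximum(depth[ok], 1e-9)
        fp = np.maximum(np.ceil(px).astype(int), 2)
    else:
        fp = np.full(ok.sum(), int(footprint))
    u0 = np.floor(uv[ok, 0] - (fp - 1) / 2.0).astype(int)
    v0 = np.floor(uv[ok, 1] - (fp - 1) / 2.0).astype(int)
    for size in np.unique(fp):
        sel = fp == size
        for du in range(size):
            for dv in range(size):
                u = u0[sel] + du
                v = v0[sel] + dv
                good = (u >= 0) & (u < w) & (v >= 0) & (v < h)
                mask[v[good], u[good]] = True
    return mask


def concordance(original: np.ndarray, reprojection: np.ndarray) -> float:
    """Jaccard overlap |A ∩ B| / |A ∪ B| of two binary masks.

    Symmetric, in [0, 1], and 1 iff the foregrounds are identical.  Two
    empty masks score 1 (with a warning).  The Dice coefficient can be
    substituted by callers needing it; the 0.8 QC threshold here is
    defined on Jaccard.
    """
    a = np.asarray(original, dtype=bool)
    b = np.asarray(reprojection, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have equal dimensions")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty; concordance defined as 1")
        return 1.0
    inter = np.logical_and(a, b).sum()
    return float(inter) / float(union)


@dataclass
class QCResult:
    passed: bool
    per_view: list[float]
    reason: str | None = None
    threshold: float = 0.8


def qc_reconstruction(
    grid: VoxelGrid,
    masks: list[np.ndarray],
    cameras: list[CameraModel],
    threshold: float = 0.8,
) -> QCResult:
    """Score reprojection concordance per view; fail the reconstruction
    if any view scores below the threshold (default 0.8), recording the
    failure class."""
    if len(masks) != len(cameras):
        raise ValueError("mask/camera count mismatch")
    if any(not np.asarray(m).any() for m in masks):
        scores = [0.0 if not np.asarray(m).any() else 1.0 for m in masks]
        return QCResult(passed=False, per_view=scores, reason=REASON_NO_PLANT, threshold=threshold)
    scores = [concordance(m, reproject(grid, cam)) for m, cam in zip(masks, cameras)]
    if min(scores) < threshold:
        return QCResult(
            passed=False, per_view=scores, reason=REASON_LOW_CONCORDANCE, threshold=threshold
        )
    return QCResult(passed=True, per_view=scores, threshold=threshold)
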