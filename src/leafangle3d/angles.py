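"""Leaf insertion angles from PCA directions of skeleton organs.

Per leaf, two angles are measured against the stem's principal frame:

* the polar angle ``theta`` in [0, 180] degrees — the angle between the
  leaf's proximal direction and the stem's first principal direction
  (erect leaves have small theta);
* the azimuth ``phi`` in [0, 360) degrees — the angle of the leaf
  direction's horizontal-plane projection, measured from the stem's
  second principal direction, counter-clockwise when viewed from above
  (from +v1).

The stem frame (v1, v2) comes from a PCA of the stem node coordinates,
and each leaf's direction from a PCA of the first ``k`` (default 20)
skeleton voxels after the leaf-stem junction, so the measurement
reflects the insertion region near the ligule rather than the drooping
blade tip.  Note theta is defined relative to the stem axis, not
gravity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .organs import PlantSegmentation

_EPS = 1e-9


@dataclass(frozen=True)
class StemFrame:
    """Orthonormal stem frame: v1 = principal direction (oriented
    upward, ``v1_z >= 0``), v2 = second principal direction with a
    deterministic sign (``v2 . x >= 0``, ties broken on y)."""

    v1: np.ndarray
    v2: np.ndarray
    degenerate: bool = False

    @property
    def v3(self) -> np.ndarray:
        return np.cross(self.v1, self.v2)


@dataclass
class LeafAngleRecord:
    plant_id: str
    timepoint: int
    leaf_index: int
    theta: float
    phi: float | None
    junction_height: float
    n_voxels_used: int
    flags: str = ""


def _orient_sign(v: np.ndarray, order=(2, 0, 1)) -> np.ndarray:
    """Flip v so its first non-negligible component among the given axis
    order is positive (default: z, then x, then y)."""
    for ax in order:
        if abs(v[ax]) > _EPS:
            return v if v[ax] > 0 else -v
    return v


def stem_frame(stem_coords: np.ndarray) -> StemFrame:
    """PCA frame of the stem node coordinates.

    Needs >= 3 nodes.  For an exactly collinear stem the second
    principal direction is undefined; a fixed horizontal direction
    orthogonal to v1 is substituted and the frame flagged degenerate.
    """
    c = np.asarray(stem_coords, dtype=float).reshape(-1, 3)
    if len(c) < 3:
        raise ValueError("stem PCA needs at least 3 nodes")
    cc = c - c.mean(axis=0)
    u, s, vt = np.linalg.svd(cc, full_matrices=False)
    v1 = _orient_sign(vt[0], order=(2, 0, 1))
    degenerate = s[1] <= max(s[0], 1.0) * 1e-9
    if degenerate:
        x = np.array([1.0, 0.0, 0.0])
        v2 = x - (x @ v1) * v1
        if np.linalg.norm(v2) < _EPS:
            y = np.array([0.0, 1.0, 0.0])
            v2 = y - (y @ v1) * v1
        v2 /= np.linalg.norm(v2)
    else:
        v2 = vt[1]
    v2 = _orient_sign(v2, order=(0, 1, 2))
    return StemFrame(v1=v1, v2=v2, degenerate=degenerate)


def leaf_direction(leaf_coords: np.ndarray, k: int = 20) -> tuple[np.ndarray, int] | None:
    """Principal direction of the first ``min(k, n)`` leaf nodes
    (ordered from the junction), sign-oriented to point away from the
    junction.  Returns ``(unit vector, n_used)`` or None for a leaf with
    fewer than 2 nodes."""
    c = np.asarray(leaf_coords, dtype=float).reshape(-1, 3)
    if len(c) < 2:
        warnings.warn("leaf with fewer than 2 nodes skipped")
        return None
    use = c[: min(k, len(c))]
    cc = use - use.mean(axis=0)
    _, _, vt = np.linalg.svd(cc, full_matrices=False)
    v = vt[0]
    away = use.mean(axis=0) - c[0]  # junction -> centroid of used nodes
    if np.linalg.norm(away) > _EPS and v @ away < 0:
        v = -v
    return v / np.linalg.norm(v), len(use)


def polar_angle(frame: StemFrame, v_leaf: np.ndarray) -> float:
    """theta = arccos(v_leaf . v1) in degrees, in [0, 180]."""
    v = np.asarray(v_leaf, dtype=float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise ValueError("zero leaf direction vector")
    return float(np.degrees(np.arccos(np.clip((v / n) @ frame.v1, -1.0, 1.0))))


def azimuth_angle(frame: StemFrame, v_leaf: np.ndarray) -> float | None:
    """phi in [0, 360): signed angle from v2 to the projection of the
    leaf direction onto the stem's cross-sectional plane, rotating
    counter-clockwise about v1 (viewed from +v1).  Returns None when the
    leaf direction is parallel to the stem axis (projection vanishes)."""
    v = np.asarray(v_leaf, dtype=float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise ValueError("zero leaf direction vector")
    v = v / n
    p = v - (v @ frame.v1) * frame.v1
    if np.linalg.norm(p) < 1e-9:
        return None
    phi = np.degrees(np.arctan2(p @ frame.v3, p @ frame.v2))
    return float(phi % 360.0)


def measure_plant(
    seg: PlantSegmentation,
    plant_id: str = "plant",
    timepoint: int = 0,
    k: int = 20,
    max_leaf_index: int = 7,
) -> list[LeafAngleRecord]:
    """One angle record per segmented leaf.

    Leaves above ``max_leaf_index`` (default 7 — upper leaves are
    typically immature and unreliable) are flagged ``above-cap`` but
    still reported.  Leaves whose direction projection is parallel to
    the stem have phi recorded as missing.
    """
    skel = seg.skeleton
    if not seg.leaves:
        return []
    frame = stem_frame(skel.coords[sorted(seg.stem_nodes)])
    records = []
    for i, leaf in enumerate(seg.leaves, start=1):
        res = leaf_direction(skel.coords[leaf.nodes], k=k)
        if res is None:
            continue
        v, n_used = res
        theta = polar_angle(frame, v)
        phi = azimuth_angle(frame, v)
        flags = []
        if i > max_leaf_index:
            flags.append("above-cap")
        if phi is None:
            flags.append("phi-undefined")
        if frame.degenerate:
            flags.append("stem-degenerate")
        records.append(
            LeafAngleRecord(
                plant_id=plant_id,
                timepoint=timepoint,
                leaf_index=i,
                theta=theta,
                phi=phi,
                junction_height=leaf.junction_height,
                n_voxels_used=n_used,
                flags=";".join(flags),
            )
        )
    return records


def records_to_frame(records: list[LeafAngleRecord]) -> pd.DataFrame:
    """Long-format table, angles rounded to 2 decimals."""
    return pd.DataFrame(
        [
            {
                "plant_id": r.plant_id,
                "timepoint": r.timepoint,
                "leaf_index": r.leaf_index,
                "theta_deg": round(r.theta, 2),
                "phi_deg": round(r.phi, 2) if r.phi is not None else np.nan,
                "junction_height_mm": round(r.junction_height, 3),
                "n_voxels_used": r.n_voxels_used,
                "flags": r.flags,
            }
            for r in records
        ]
    )
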