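"""Parametric synthetic plants with known leaf geometry.

Generates sorghum-like single-stem plants — a near-vertical stem with
leaves inserted at increasing heights — renders calibrated multi-view
binary silhouettes of them, and reports the true insertion angles, so
that every downstream stage (carving, skeletonization, segmentation,
angle measurement) can be validated against known ground truth.

Leaves are tubes of constant thickness along a parametric curve whose
initial tangent realizes the true polar/azimuth angles; the optional
droop (curvature) bends only the distal part of the blade, so the
proximal segment used for angle measurement stays straight, mirroring
how insertion angle is defined at the ligule region of a real leaf.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.morphology import closing as _binary_closing, disk as _disk_selem

from .cameras import CameraModel, DEFAULT_VOLUME_SIDE_MM


@dataclass(frozen=True)
class LeafSpec:
    """Geometry of one leaf.

    insertion_height : mm along the stem from the base.
    polar_angle_true : degrees in [0, 180]; angle between the leaf's
        proximal direction and the stem axis (0 = fully erect).
    azimuth_true : degrees in [0, 360); direction of the leaf around the
        stem, measured in the stem's cross-sectional plane.
    length : blade length, mm.
    curvature : dimensionless droop; 0 = straight blade, 1 = strong
        distal droop.  Only the distal 60% of the blade bends.
    thickness : blade tube diameter, mm.
    """

    insertion_height: float
    polar_angle_true: float
    azimuth_true: float
    length: float = 150.0
    curvature: float = 0.0
    thickness: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.polar_angle_true <= 180.0):
            raise ValueError("polar_angle_true must be in [0, 180]")
        if not (0.0 <= self.azimuth_true < 360.0):
            raise ValueError("azimuth_true must be in [0, 360)")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class PlantModel:
    """A generated plant: stem polyline (mm, base first), leaves ordered
    by strictly increasing insertion height, and the seed that produced
    it."""

    stem_polyline: np.ndarray
    leaves: tuple[LeafSpec, ...]
    seed: int
    stem_radius: float = 9.0

    def __post_init__(self) -> None:
        poly = np.asarray(self.stem_polyline, dtype=float)
        object.__setattr__(self, "stem_polyline", poly)
        if poly.ndim != 2 or poly.shape[1] != 3 or len(poly) < 2:
            raise ValueError("stem_polyline must be an (N>=2, 3) array")
        if np.argmin(poly[:, 2]) != 0:
            raise ValueError("stem base must have the minimum height")
        heights = [lf.insertion_height for lf in self.leaves]
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise ValueError("leaf insertion heights must be strictly increasing")

    # -- construction helpers ------------------------------------------
    @property
    def stem_axis(self) -> np.ndarray:
        """Unit vector from stem base to tip."""
        d = self.stem_polyline[-1] - self.stem_polyline[0]
        return d / np.linalg.norm(d)

    def stem_point_at(self, height: float) -> np.ndarray:
        """Point on the stem polyline at the given arc height (mm from base)."""
        seg = np.diff(self.stem_polyline, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        h = np.clip(height, 0.0, cum[-1])
        i = int(np.searchsorted(cum, h, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (h - cum[i]) / seglen[i]
        return self.stem_polyline[i] + t * seg[i]

    def leaf_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal construction frame (e1 = stem axis up, e2, e3)
        used to realize the true angles."""
        e1 = self.stem_axis
        x = np.array([1.0, 0.0, 0.0])
        e2 = x - (x @ e1) * e1
        n = np.linalg.norm(e2)
        if n < 1e-9:
            y = np.array([0.0, 1.0, 0.0])
            e2 = y - (y @ e1) * e1
            n = np.linalg.norm(e2)
        e2 /= n
        e3 = np.cross(e1, e2)
        return e1, e2, e3

    def leaf_centerline(self, leaf: LeafSpec, spacing: float = 2.0) -> np.ndarray:
        """Sampled 3D centerline of a leaf, from the stem junction outward."""
        e1, e2, e3 = self.leaf_frame()
        th = np.deg2rad(leaf.polar_angle_true)
        ph = np.deg2rad(leaf.azimuth_true)
        d0 = np.cos(th) * e1 + np.sin(th) * (np.cos(ph) * e2 + np.sin(ph) * e3)
        start = self.stem_point_at(leaf.insertion_height)
        n = max(int(np.ceil(leaf.length / spacing)) + 1, 2)
        s = np.linspace(0.0, leaf.length, n)
        if leaf.curvature == 0.0:
            return start + s[:, None] * d0
        # distal droop: rotate the tangent toward -e1 past 40% of length
        bend_axis = np.cross(d0, -e1)
        bn = np.linalg.norm(bend_axis)
        if bn < 1e-9:  # leaf parallel to stem axis: droop in the e2 plane
            bend_axis = e2
        else:
            bend_axis = bend_axis / bn
        pts = [start]
        p = start.copy()
        d = d0.copy()
        max_bend = leaf.curvature * np.deg2rad(90.0)
        for a, b in zip(s, s[1:]):
            frac = max(0.0, (b / leaf.length - 0.4) / 0.6)
            ang = max_bend * frac * (b - a) / (leaf.length * 0.6)
            d = _rotate_about(d, bend_axis, ang)
            p = p + d * (b - a)
            pts.append(p.copy())
        return np.asarray(pts)

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "stem_polyline": self.stem_polyline.tolist(),
            "leaves": [asdict(lf) for lf in self.leaves],
            "seed": self.seed,
            "stem_radius": self.stem_radius,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, src: str | Path) -> "PlantModel":
        p = Path(src)
        text = p.read_text() if p.exists() else str(src)
        d = json.loads(text)
        return cls(
            stem_polyline=np.asarray(d["stem_polyline"], dtype=float),
            leaves=tuple(LeafSpec(**lf) for lf in d["leaves"]),
            seed=int(d["seed"]),
            stem_radius=float(d.get("stem_radius", 9.0)),
        )


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def generate_plant(
    n_leaves: int,
    angle_ranges: tuple[float, float] | list[tuple[float, float]] | None = None,
    seed: int = 0,
    stem_height: float = 450.0,
    stem_lean_deg: float = 1.5,
    stem_radius: float = 9.0,
    first_insertion: float = 80.0,
    top_insertion_frac: float = 0.97,
    length_range: tuple[float, float] = (120.0, 200.0),
    curvature_range: tuple[float, float] = (0.0, 0.0),
    leaf_thickness: float = 8.0,
    azimuth_jitter_deg: float = 30.0,
) -> PlantModel:
    """Generate a deterministic random plant.

    Leaves are placed at strictly increasing insertion heights between
    ``first_insertion`` and ``top_insertion_frac * stem_height``; the
    default puts the youngest leaf near the stem apex, as in a real
    grass where the top of the culm is the whorl from which the
    youngest leaf emerges.  Polar
    angles are drawn uniformly from ``angle_ranges`` (a single (lo, hi)
    pair applied to all leaves, or one pair per leaf; default (20, 70)
    degrees, typical of sorghum insertion angles).  Azimuths follow an
    alternate (distichous) phyllotaxy — successive leaves on opposite
    sides of the stem — with uniform jitter, which also keeps silhouettes
    well separated across the five side views.
    """
    if n_leaves < 0:
        raise ValueError("n_leaves must be non-negative")
    rng = np.random.default_rng(seed)
    if angle_ranges is None:
        ranges = [(20.0, 70.0)] * n_leaves
    elif isinstance(angle_ranges, tuple) and np.isscalar(angle_ranges[0]):
        ranges = [angle_ranges] * n_leaves
    else:
        ranges = list(angle_ranges)
        if len(ranges) != n_leaves:
            raise ValueError("need one angle range per leaf")

    lean = np.deg2rad(stem_lean_deg) * rng.random()
    lean_dir = rng.uniform(0, 2 * np.pi)
    axis = np.array(
        [np.sin(lean) * np.cos(lean_dir), np.sin(lean) * np.sin(lean_dir), np.cos(lean)]
    )
    t = np.linspace(0.0, stem_height, max(int(stem_height / 5.0), 2))
    stem = t[:, None] * axis  # base at origin (pot center)

    leaves = []
    if n_leaves > 0:
        span_lo, span_hi = first_insertion, top_insertion_frac * stem_height
        base_heights = np.linspace(span_lo, span_hi, n_leaves)
        gap = (span_hi - span_lo) / max(n_leaves - 1, 1)
        heights = base_heights + rng.uniform(-0.25, 0.25, size=n_leaves) * gap
        heights = np.sort(heights)
        # keep insertions on the stem and strictly increasing
        heights[-1] = min(heights[-1], top_insertion_frac * stem_height)
        for i in range(n_leaves - 2, -1, -1):
            heights[i] = min(heights[i], heights[i + 1] - 2.0)
        phyllo0 = rng.uniform(0.0, 360.0)
        for i in range(n_leaves):
            lo, hi = ranges[i]
            polar = rng.uniform(lo, hi)
            az = (phyllo0 + 180.0 * i + rng.uniform(-1, 1) * azimuth_jitter_deg) % 360.0
            leaves.append(
                LeafSpec(
                    insertion_height=float(heights[i]),
                    polar_angle_true=float(polar),
                    azimuth_true=float(az),
                    length=float(rng.uniform(*length_range)),
                    curvature=float(rng.uniform(*curvature_range)),
                    thickness=leaf_thickness,
                )
            )
    return PlantModel(stem_polyline=stem, leaves=tuple(leaves), seed=seed, stem_radius=stem_radius)


def _centerline_samples(model: PlantModel, spacing: float = 2.0):
    """All (point, tube radius) samples describing the plant solid."""
    pts = [model.stem_polyline]
    radii = [np.full(len(model.stem_polyline), model.stem_radius)]
    # resample stem at the requested spacing
    seg = np.diff(model.stem_polyline, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    n = max(int(total / spacing) + 1, 2)
    hs = np.linspace(0.0, total, n)
    stem_pts = np.array([model.stem_point_at(h) for h in hs])
    pts = [stem_pts]
    radii = [np.full(len(stem_pts), model.stem_radius)]
    for leaf in model.leaves:
        cl = model.leaf_centerline(leaf, spacing=spacing)
        pts.append(cl)
        radii.append(np.full(len(cl), leaf.thickness / 2.0))
    return np.concatenate(pts), np.concatenate(radii)


def render_silhouettes(
    model: PlantModel,
    cameras: list[CameraModel],
    spacing: float = 2.0,
    margin_px: float = 1.0,
) -> list[np.ndarray]:
    """Render one binary silhouette per camera.

    The tube geometry is point-sampled along the centerlines and each
    sample is splatted as a disk of its projected tube radius (plus a
    small anti-gap margin); small holes are closed morphologically.
    Returns boolean arrays of shape (height, width).
    """
    if not cameras:
        raise ValueError("need at least one camera")
    points, radii = _centerline_samples(model, spacing=spacing)
    masks = []
    any_visible = False
    for cam in cameras:
        w, h = cam.image_size
        mask = np.zeros((h, w), dtype=bool)
        uv, depth = cam.project(points)
        ok = depth > 1.0
        if ok.any():
            r_px = cam.focal_length * radii[ok] / depth[ok] + margin_px
            us, vs = uv[ok, 0], uv[ok, 1]
            for u, v, r in zip(us, vs, r_px):
                if u < -r or u >= w + r or v < -r or v >= h + r:
                    continue
                rr, cc = _draw_disk((v, u), r, shape=mask.shape)
                mask[rr, cc] = True
                any_visible = True
        if mask.any():
            mask = _binary_closing(mask, _disk_selem(2))
        masks.append(mask)
    if points.size and not any_visible:
        warnings.warn("plant is outside all view frusta; all masks empty")
    return masks


def ground_truth_angles(model: PlantModel, plant_id: str = "synthetic", timepoint: int = 0):
    """True per-leaf angle records, ordered (and 1-indexed) by the height
    of the leaf-stem junction, lowest leaf first."""
    from .angles import LeafAngleRecord

    order = np.argsort([lf.insertion_height for lf in model.leaves], kind="stable")
    records = []
    for rank, i in enumerate(order, start=1):
        lf = model.leaves[i]
        records.append(
            LeafAngleRecord(
                plant_id=plant_id,
                timepoint=timepoint,
                leaf_index=rank,
                theta=lf.polar_angle_true,
                phi=lf.azimuth_true,
                junction_height=float(model.stem_point_at(lf.insertion_height)[2]),
                n_voxels_used=0,
            )
        )
    return records


def save_silhouettes(masks, cameras, out_dir: str | Path, plant_id: str = "plant") -> list[Path]:
    """Write masks as 8-bit PNGs named ``<plant>_<view_deg>.png`` (top
    view ``<plant>_top.png``); 0 = background, 255 = plant."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for mask, cam in zip(masks, cameras):
        name = (
            f"{plant_id}_top.png"
            if cam.view_kind == "top"
            else f"{plant_id}_{int(round(cam.turntable_angle))}.png"
        )
        p = out / name
        Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(p)
        paths.append(p)
    return paths


def load_silhouette(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 127
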