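"""End-to-end convenience driver: silhouettes in, leaf angles out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import LeafAngleRecord, measure_plant
from .carving import QCResult, VoxelGrid, carve, qc_reconstruction
from .cameras import CameraModel
from .organs import PlantSegmentation, segment
from .skeleton import CurveSkeleton, StemBase, connect_components, find_stem_base, prune


@dataclass
class PipelineResult:
    grid: VoxelGrid
    skeleton: CurveSkeleton
    base: StemBase
    segmentation: PlantSegmentation | None
    records: list[LeafAngleRecord]
    qc: QCResult
    ok: bool
    failure_reason: str | None = None


def reconstruct_and_measure(
    masks: list[np.ndarray],
    cameras: list[CameraModel],
    resolution: int = 512,
    side: float | None = None,
    plant_id: str = "plant",
    timepoint: int = 0,
    concordance_threshold: float = 0.8,
    min_branch_len: int = 10,
    min_branch_straightness: float = 0.5,
    k_voxels: int = 20,
    max_leaf_index: int = 7,
) -> PipelineResult:
    """Run carve -> QC -> thin -> prune -> connect -> base -> segment ->
    measure on one plant's silhouettes.

    QC failures (no plant, low reprojection concordance, no confident
    soil-stem junction) abort the measurement but still return all
    intermediate products for inspection.
    """
    from .skeleton import thin

    kwargs = {} if side is None else {"side": side}
    grid = carve(masks, cameras, resolution=resolution, **kwargs)
    qc = qc_reconstruction(grid, masks, cameras, threshold=concordance_threshold)
    skel = thin(grid)
    skel = prune(skel, min_branch_len=min_branch_len, min_branch_straightness=min_branch_straightness)
    skel = connect_components(skel)
    base = find_stem_base(skel)
    if not qc.passed:
        return PipelineResult(grid, skel, base, None, [], qc, ok=False, failure_reason=qc.reason)
    if not base.ok:
        return PipelineResult(grid, skel, base, None, [], qc, ok=False, failure_reason=base.reason)
    seg = segment(skel, base)
    records = measure_plant(
        seg, plant_id=plant_id, timepoint=timepoint, k=k_voxels, max_leaf_index=max_leaf_index
    )
    return PipelineResult(grid, skel, base, seg, records, qc, ok=True)
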