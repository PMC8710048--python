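import numpy as np
import pytest

import leafangle3d as la
from leafangle3d.carving import VoxelGrid


@pytest.fixture(scope="session")
def rig():
    return la.default_rig()


def grid_from_occupancy(occ: np.ndarray, side: float = 600.0) -> VoxelGrid:
    """Embed a boolean array into a cubic VoxelGrid (padded with zeros)."""
    occ = np.asarray(occ, dtype=bool)
    r = max(occ.shape)
    cube = np.zeros((r, r, r), dtype=bool)
    cube[: occ.shape[0], : occ.shape[1], : occ.shape[2]] = occ
    return VoxelGrid(resolution=r, side=side, occupancy=cube)


@pytest.fixture(scope="session")
def plant_recon(rig):
    """One clean 4-leaf synthetic plant run through the full pipeline at
    R=128; shared by segmentation/angle tests."""
    model = la.generate_plant(n_leaves=4, seed=11)
    masks = la.render_silhouettes(model, rig)
    res = la.reconstruct_and_measure(masks, rig, resolution=128, plant_id="fixture")
    return model, masks, res
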