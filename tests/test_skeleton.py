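import numpy as np
import pytest

from conftest import grid_from_occupancy
from leafangle3d.carving import VoxelGrid
from leafangle3d.skeleton import (
    connect_components,
    find_stem_base,
    prune,
    thin,
    thin_occupancy,
)


def degree_census(skel):
    from collections import Counter

    return Counter(d for _, d in skel.graph.degree())


# ----------------------------------------------------------------------
# thinning
# ----------------------------------------------------------------------
def test_thin_empty_grid():
    skel = thin(VoxelGrid(resolution=16))
    assert skel.n_nodes == 0
    assert skel.n_components() == 0


def test_thin_single_voxel_curve_is_fixed_point():
    occ = np.zeros((60, 9, 9), dtype=bool)
    occ[5:55, 4, 4] = True
    grid = grid_from_occupancy(occ)
    skel = thin(grid)
    assert skel.n_nodes == 50
    assert np.array_equal(np.sort(skel.indices, axis=0), np.argwhere(occ))
    # idempotence: thinning the skeleton changes nothing
    again = thin(grid_from_occupancy(thin_occupancy(occ)))
    assert again.n_nodes == skel.n_nodes


def test_thin_solid_box_yields_single_path():
    """A 5x5x50 box reduces to one simple path: two endpoints, interior
    all degree 2, endpoints inside the end caps."""
    occ = np.zeros((12, 12, 60), dtype=bool)
    occ[3:8, 3:8, 5:55] = True
    skel = thin(grid_from_occupancy(occ))
    census = degree_census(skel)
    assert census[1] == 2
    assert census[2] == skel.n_nodes - 2
    assert not skel.junctions()
    zs = skel.indices[[n for n, d in skel.graph.degree() if d == 1], 2]
    assert zs.min() <= 10 and zs.max() >= 49
    # skeleton nodes are a subset of the input voxels
    assert all(occ[tuple(v)] for v in skel.indices)


@pytest.mark.parametrize("width", [2, 4, 6])
def test_thin_preserves_even_width_limbs(width):
    """Even cross-sections must reduce to a centerline, not vanish."""
    occ = np.zeros((width + 8, width + 8, 40), dtype=bool)
    occ[4 : 4 + width, 4 : 4 + width, 2 : 32] = True
    skel = thin(grid_from_occupancy(occ))
    zs = skel.indices[:, 2]
    assert skel.n_nodes >= 20
    # most of the 30-voxel extent survives (caps erode by about the limb radius)
    assert zs.max() - zs.min() >= 30 - 2 * (width // 2 + 1)
    assert skel.n_components() == 1


def test_thin_preserves_component_count():
    occ = np.zeros((40, 40, 40), dtype=bool)
    zz, yy, xx = np.mgrid[:40, :40, :40]
    occ |= (xx - 10) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2 < 36
    occ |= (xx - 30) ** 2 + (yy - 30) ** 2 + (zz - 30) ** 2 < 36
    skel = thin(grid_from_occupancy(occ))
    assert skel.n_components() == 2


def test_thin_output_is_one_voxel_thick():
    occ = np.zeros((20, 20, 40), dtype=bool)
    occ[4:16, 4:16, 2:38] = True
    skel = thin(grid_from_occupancy(occ))
    lookup = {tuple(v) for v in skel.indices}
    for v in skel.indices:
        n26 = sum(
            (v[0] + dx, v[1] + dy, v[2] + dz) in lookup
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        )
        assert n26 < 26  # no fully occupied neighbourhood


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------
def _line(occ, p0, p1):
    p0, p1 = np.asarray(p0), np.asarray(p1)
    n = int(np.abs(p1 - p0).max()) + 1
    for t in np.linspace(0, 1, n):
        occ[tuple(np.round(p0 + t * (p1 - p0)).astype(int))] = True


def test_prune_removes_short_spur_keeps_trunk():
    occ = np.zeros((110, 9, 9), dtype=bool)
    occ[2:102, 4, 4] = True  # 100-voxel trunk
    _line(occ, (50, 4, 4), (50, 7, 4))  # 3-voxel spur
    skel = thin(grid_from_occupancy(occ))
    assert len(skel.endpoints()) == 3
    pruned = prune(skel, min_branch_len=10)
    assert len(pruned.endpoints()) == 2
    assert pruned.n_nodes >= 100  # trunk intact
    assert not pruned.junctions()


def test_prune_is_fixed_point_without_short_branches():
    occ = np.zeros((110, 9, 9), dtype=bool)
    occ[2:102, 4, 4] = True
    skel = thin(grid_from_occupancy(occ))
    pruned = prune(skel, min_branch_len=10)
    assert pruned.n_nodes == skel.n_nodes


def test_prune_keeps_star_of_long_arms():
    occ = np.zeros((120, 120, 120), dtype=bool)
    c = (60, 60, 60)
    for tip in [(10, 60, 60), (110, 60, 60), (60, 10, 60), (60, 110, 60), (60, 60, 110)]:
        _line(occ, c, tip)
    skel = thin(grid_from_occupancy(occ))
    pruned = prune(skel, min_branch_len=10)
    assert len(pruned.endpoints()) == 5


def test_prune_removes_crooked_branch_by_straightness():
    occ = np.zeros((110, 30, 12), dtype=bool)
    occ[2:102, 4, 4] = True
    # a 23-voxel serpentine spur: long enough, but end-to-end/path < 0.5;
    # strands spaced 2 voxels apart so thinning sees no shortcuts
    path = [(50, 4, 4)]
    steps = [(0, 1, 0)] * 6 + [(0, 0, 1)] * 2 + [(0, -1, 0)] * 6
    steps += [(0, 0, 1)] * 2 + [(0, 1, 0)] * 6
    for s in steps:
        path.append(tuple(np.add(path[-1], s)))
    for p in path[1:]:
        occ[p] = True
    skel = thin(grid_from_occupancy(occ))
    pruned = prune(skel, min_branch_len=10, min_branch_straightness=0.5)
    assert len(pruned.endpoints()) == 2
    assert not pruned.junctions()


def test_prune_never_removes_longest_path():
    occ = np.zeros((30, 9, 9), dtype=bool)
    occ[2:28, 4, 4] = True  # a lone 26-voxel curve
    skel = thin(grid_from_occupancy(occ))
    pruned = prune(skel, min_branch_len=100)  # would exceed every branch
    assert pruned.n_nodes == skel.n_nodes


# ----------------------------------------------------------------------
# component connection
# ----------------------------------------------------------------------
def test_connect_already_connected_is_identity():
    occ = np.zeros((30, 9, 9), dtype=bool)
    occ[2:28, 4, 4] = True
    skel = thin(grid_from_occupancy(occ))
    joined = connect_components(skel)
    assert joined.n_nodes == skel.n_nodes
    assert joined.n_components() == 1


def test_connect_two_components_adds_flagged_connector():
    occ = np.zeros((40, 9, 9), dtype=bool)
    occ[2:15, 4, 4] = True
    occ[20:38, 4, 4] = True  # 5-voxel gap
    skel = thin(grid_from_occupancy(occ))
    assert skel.n_components() == 2
    joined = connect_components(skel)
    assert joined.n_components() == 1
    assert joined.synthetic.any()
    assert not skel.synthetic.any()  # input untouched


def test_connect_three_components_adds_two_bridges():
    occ = np.zeros((60, 9, 9), dtype=bool)
    occ[2:12, 4, 4] = True
    occ[20:30, 4, 4] = True
    occ[40:58, 4, 4] = True
    skel = thin(grid_from_occupancy(occ))
    assert skel.n_components() == 3
    joined = connect_components(skel)
    assert joined.n_components() == 1
    # spanning-tree bridging: edges == nodes - 1 for the resulting tree
    assert joined.graph.number_of_edges() == joined.n_nodes - 1


# ----------------------------------------------------------------------
# stem base
# ----------------------------------------------------------------------
def test_stem_base_on_vertical_stem():
    occ = np.zeros((9, 9, 60), dtype=bool)
    occ[4, 4, 2:55] = True
    _line(occ, (4, 4, 30), (8, 4, 45))  # one leaf
    skel = thin(grid_from_occupancy(occ))
    base = find_stem_base(skel)
    assert base.ok
    assert base.confidence > 0.9
    assert skel.coords[base.node][2] == skel.coords[:, 2].min()


def test_stem_base_fails_on_horizontal_skeleton():
    occ = np.zeros((60, 9, 9), dtype=bool)
    occ[2:55, 4, 4] = True  # lies along x: nothing vertical
    skel = thin(grid_from_occupancy(occ))
    base = find_stem_base(skel)
    assert not base.ok
    assert base.reason == "no-stem-junction"


def test_stem_base_prefers_vertical_branch_over_tiller():
    """Two low endpoints: the more vertical basal branch wins."""
    occ = np.zeros((40, 9, 60), dtype=bool)
    occ[4, 4, 3:55] = True  # vertical stem, endpoint at z=3
    _line(occ, (4, 4, 12), (24, 4, 4))  # oblique tiller ending low at z=4
    skel = thin(grid_from_occupancy(occ))
    base = find_stem_base(skel, vertical_tol_deg=30.0)
    assert base.ok
    idx = skel.indices[base.node]
    assert idx[0] == 4  # the stem endpoint, not the tiller tip
    assert idx[2] <= 5


def test_empty_skeleton_has_no_base():
    skel = thin(VoxelGrid(resolution=8))
    base = find_stem_base(skel)
    assert not base.ok


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------
def test_skeleton_exports(tmp_path):
    occ = np.zeros((30, 9, 9), dtype=bool)
    occ[2:28, 4, 4] = True
    skel = thin(grid_from_occupancy(occ))
    nodes = tmp_path / "nodes.csv"
    edges = tmp_path / "edges.csv"
    obj = tmp_path / "skel.obj"
    skel.to_csv(nodes)
    skel.edges_to_csv(edges)
    skel.to_obj(obj)
    import pandas as pd

    ndf = pd.read_csv(nodes)
    assert len(ndf) == skel.n_nodes
    assert set(["x_mm", "y_mm", "z_mm", "degree", "branch", "synthetic"]) <= set(ndf.columns)
    edf = pd.read_csv(edges)
    assert len(edf) == skel.graph.number_of_edges()
    text = obj.read_text()
    assert text.count("\nv ") + text.startswith("v ") == skel.n_nodes
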