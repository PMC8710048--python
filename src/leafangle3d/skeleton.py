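"""Curve skeletonization of carved voxel grids.

The occupancy set is reduced to a one-voxel-thick curve skeleton by
topology-preserving iterative thinning (Lee et al.'s medial-axis
thinning as implemented in scikit-image), represented as a graph of
voxel-center nodes with 26-adjacency edges.  Post-processing removes
spurious terminal branches (too short or too crooked to be a leaf),
joins disconnected components with flagged synthetic connector nodes,
and locates the soil-stem junction — the basal endpoint whose incident
branch runs near-vertically — which anchors organ segmentation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .carving import VoxelGrid, REASON_NO_STEM_JUNCTION

_NEIGH_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)


@dataclass
class CurveSkeleton:
    """Graph of skeleton voxels.

    ``graph`` is an undirected networkx graph whose nodes are integers
    indexing ``indices`` (voxel indices) / ``coords`` (world mm).
    Connector nodes inserted by :func:`connect_components` are flagged
    in ``synthetic``.  Branches — maximal simple paths between nodes of
    degree != 2 — are recomputed on demand.
    """

    indices: np.ndarray  # (N, 3) int voxel indices
    coords: np.ndarray  # (N, 3) float world mm
    graph: nx.Graph
    synthetic: np.ndarray  # (N,) bool
    voxel_size: float = 1.0
    resolution: int = 0
    side: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def degrees(self) -> dict[int, int]:
        return dict(self.graph.degree())

    def endpoints(self) -> list[int]:
        return [n for n, d in self.graph.degree() if d == 1]

    def junctions(self) -> list[int]:
        return [n for n, d in self.graph.degree() if d >= 3]

    def n_components(self) -> int:
        if self.n_nodes == 0:
            return 0
        return nx.number_connected_components(self.graph)

    def branches(self) -> list[list[int]]:
        """Maximal simple paths whose interior nodes all have degree 2.

        Endpoints of a branch are nodes of degree != 2 (curve endpoints
        or junctions); an isolated cycle is returned as a closed path.
        """
        g = self.graph
        deg = dict(g.degree())
        branch_ends = {n for n, d in deg.items() if d != 2}
        visited_edges = set()
        out: list[list[int]] = []
        for start in sorted(branch_ends, key=self._node_key):
            for nb in sorted(g.neighbors(start), key=self._node_key):
                if (start, nb) in visited_edges:
                    continue
                path = [start, nb]
                visited_edges.add((start, nb))
                visited_edges.add((nb, start))
                prev, cur = start, nb
                while deg[cur] == 2 and cur not in branch_ends:
                    nxt = next(x for x in g.neighbors(cur) if x != prev)
                    visited_edges.add((cur, nxt))
                    visited_edges.add((nxt, cur))
                    path.append(nxt)
                    prev, cur = cur, nxt
                out.append(path)
        # pure cycles (every node degree 2) not reachable from branch ends
        seen = {n for p in out for n in p}
        for comp in nx.connected_components(g):
            if not (comp & seen) and len(comp) > 0:
                comp_sorted = sorted(comp, key=self._node_key)
                start = comp_sorted[0]
                if deg[start] == 0:
                    out.append([start])
                    continue
                path = [start]
                prev, cur = None, start
                while True:
                    nbrs = [x for x in self.graph.neighbors(cur) if x != prev]
                    if not nbrs:
                        break
                    nxt = sorted(nbrs, key=self._node_key)[0]
                    if nxt == start:
                        path.append(nxt)
                        break
                    path.append(nxt)
                    prev, cur = cur, nxt
                out.append(path)
        return out

    def _node_key(self, n: int):
        """Deterministic (z, y, x) lexicographic ordering key."""
        ix, iy, iz = self.indices[n]
        return (iz, iy, ix, n)

    def branch_length_mm(self, path: list[int]) -> float:
        c = self.coords[path]
        return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())

    def subset(self, keep: set[int]) -> "CurveSkeleton":
        """Skeleton restricted to a node subset (node ids re-labelled)."""
        keep_sorted = sorted(keep)
        relabel = {old: new for new, old in enumerate(keep_sorted)}
        g = nx.Graph()
        g.add_nodes_from(range(len(keep_sorted)))
        for u, v in self.graph.edges():
            if u in relabel and v in relabel:
                g.add_edge(relabel[u], relabel[v])
        return CurveSkeleton(
            indices=self.indices[keep_sorted],
            coords=self.coords[keep_sorted],
            graph=g,
            synthetic=self.synthetic[keep_sorted],
            voxel_size=self.voxel_size,
            resolution=self.resolution,
            side=self.side,
        )

    # -- export ---------------------------------------------------------
    def to_csv(self, path: str | Path, extra_columns: dict[str, list] | None = None) -> None:
        branches = self.branches()
        branch_of = {}
        for bid, p in enumerate(branches):
            for n in p:
                branch_of.setdefault(n, bid)
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            header = ["node", "ix", "iy", "iz", "x_mm", "y_mm", "z_mm", "degree", "branch", "synthetic"]
            extra = extra_columns or {}
            header += list(extra.keys())
            wr.writerow(header)
            deg = dict(self.graph.degree())
            for n in range(self.n_nodes):
                row = [
                    n,
                    *self.indices[n].tolist(),
                    *np.round(self.coords[n], 3).tolist(),
                    deg.get(n, 0),
                    branch_of.get(n, -1),
                    int(self.synthetic[n]),
                ]
                row += [extra[k][n] for k in extra]
                wr.writerow(row)

    def edges_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["u", "v"])
            for u, v in sorted(self.graph.edges()):
                wr.writerow([u, v])

    def to_obj(self, path: str | Path) -> None:
        """Polyline OBJ (v + l records) for external 3D viewers."""
        with open(path, "w") as fh:
            for x, y, z in self.coords:
                fh.write(f"v {x:.3f} {y:.3f} {z:.3f}\n")
            for u, v in sorted(self.graph.edges()):
                fh.write(f"l {u + 1} {v + 1}\n")


def _build_skeleton(
    indices: np.ndarray, grid: VoxelGrid, synthetic: np.ndarray | None = None
) -> CurveSkeleton:
    indices = np.asarray(indices, dtype=int).reshape(-1, 3)
    coords = grid.index_to_world(indices) if len(indices) else np.zeros((0, 3))
    g = nx.Graph()
    g.add_nodes_from(range(len(indices)))
    if len(indices):
        lookup = {tuple(v): i for i, v in enumerate(indices)}
        for i, v in enumerate(indices):
            for off in _NEIGH_OFFSETS:
                j = lookup.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
                if j is not None and j > i:
                    g.add_edge(i, j)
    if synthetic is None:
        synthetic = np.zeros(len(indices), dtype=bool)
    return CurveSkeleton(
        indices=indices,
        coords=coords,
        graph=g,
        synthetic=synthetic,
        voxel_size=grid.voxel_size,
        resolution=grid.resolution,
        side=grid.side,
    )


# ----------------------------------------------------------------------
# topology-preserving curve thinning
# ----------------------------------------------------------------------
# The 3x3x3 neighbourhood is flattened C-style; cell 13 is the center.
_CELLS = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
_CENTER = 13
_N26 = [i for i in range(27) if i != _CENTER]
_N18 = [
    i
    for i, (dx, dy, dz) in enumerate(_CELLS)
    if i != _CENTER and abs(dx) + abs(dy) + abs(dz) <= 2
]
_FACES = [i for i, (dx, dy, dz) in enumerate(_CELLS) if abs(dx) + abs(dy) + abs(dz) == 1]


def _adjacency(cells_a, cells_b, kind):
    out = {i: [] for i in cells_a}
    for i in cells_a:
        ai = _CELLS[i]
        for j in cells_b:
            if i == j:
                continue
            d = [abs(a - b) for a, b in zip(ai, _CELLS[j])]
            if kind == 26 and max(d) == 1:
                out[i].append(j)
            elif kind == 6 and sum(d) == 1:
                out[i].append(j)
    return out


_ADJ26 = _adjacency(_N26, _N26, 26)
_ADJ6_18 = _adjacency(_N18, _N18, 6)


def _deletable(patch_flat: np.ndarray) -> bool:
    """Simple-point test for the center of a 3x3x3 boolean patch.

    The center is deletable iff it is not a curve endpoint (it has >= 2
    foreground 26-neighbours) and deleting it preserves local topology:
    exactly one 26-connected component of foreground in the
    26-neighbourhood, and exactly one 6-connected component of
    background in the 18-neighbourhood that touches a face neighbour
    (Bertrand & Malandain's characterization).
    """
    fg = [i for i in _N26 if patch_flat[i]]
    if len(fg) <= 1:
        return False  # endpoint or isolated voxel: never removed
    # one foreground component under 26-adjacency
    fg_set = set(fg)
    stack = [fg[0]]
    seen = {fg[0]}
    while stack:
        u = stack.pop()
        for v in _ADJ26[u]:
            if v in fg_set and v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) != len(fg_set):
        return False
    # one background 6-component in N18 touching a face neighbour
    bg = {i for i in _N18 if not patch_flat[i]}
    face_bg = [i for i in _FACES if i in bg]
    if not face_bg:
        return False  # interior voxel
    stack = [face_bg[0]]
    seen = {face_bg[0]}
    while stack:
        u = stack.pop()
        for v in _ADJ6_18[u]:
            if v in bg and v not in seen:
                seen.add(v)
                stack.append(v)
    return all(f in seen for f in face_bg)


# six face directions, ordered for symmetric directional sub-iterations
_DIRECTIONS = [(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0), (1, 0, 0), (-1, 0, 0)]

_POW2 = (1 << np.arange(27, dtype=np.int64))


def thin_occupancy(occupancy: np.ndarray) -> np.ndarray:
    """Reduce a boolean volume to its curve skeleton by sequential
    simple-point deletion with directional sub-iterations.

    Border voxels (background face-neighbour in the current direction)
    are partitioned into the eight (x, y, z)-parity subfields — voxels
    of one subfield are never 26-adjacent, so their deletions are
    independent and erosion cannot cascade along a thin limb — and each
    subfield is processed in (z, y, x) lexicographic order, removing a
    voxel when the simple-point test allows.  Topology is preserved
    exactly and the result is platform-stable.  Curve endpoints are
    never removed, which keeps limb tips in place.
    """
    work = np.pad(np.asarray(occupancy, dtype=bool), 1)
    cache: dict[int, bool] = {}
    changed = True
    while changed:
        changed = False
        for dx, dy, dz in _DIRECTIONS:
            cand = work.copy()
            # background face-neighbour in direction d
            nb = np.zeros_like(work)
            nb[
                max(0, -dx) : work.shape[0] - max(0, dx),
                max(0, -dy) : work.shape[1] - max(0, dy),
                max(0, -dz) : work.shape[2] - max(0, dz),
            ] = work[
                max(0, dx) : work.shape[0] + min(0, dx),
                max(0, dy) : work.shape[1] + min(0, dy),
                max(0, dz) : work.shape[2] + min(0, dz),
            ]
            cand &= ~nb
            idx = np.argwhere(cand)
            if len(idx) == 0:
                continue
            parity = (idx[:, 0] % 2) * 4 + (idx[:, 1] % 2) * 2 + idx[:, 2] % 2
            order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2], parity))
            for i in order:
                x, y, z = idx[i]
                if not work[x, y, z]:
                    continue
                patch = work[x - 1 : x + 2, y - 1 : y + 2, z - 1 : z + 2].ravel()
                key = int(patch @ _POW2)
                res = cache.get(key)
                if res is None:
                    res = _deletable(patch)
                    cache[key] = res
                if res:
                    work[x, y, z] = False
                    changed = True
    return work[1:-1, 1:-1, 1:-1]


def thin(grid: VoxelGrid) -> CurveSkeleton:
    """Iteratively thin the occupancy to a one-voxel-thick curve skeleton.

    Topology preserving: each connected component of the input yields
    one skeleton component, and skeleton voxels are a subset of the
    input voxels.  An empty grid yields an empty skeleton.
    """
    if grid.count == 0:
        return _build_skeleton(np.zeros((0, 3), dtype=int), grid)
    skel = thin_occupancy(grid.occupancy)
    return _build_skeleton(np.argwhere(skel), grid)


def _longest_path_nodes(skel: CurveSkeleton) -> set[int]:
    """Nodes on a longest (mm-weighted) simple path of the largest
    component — the main root-to-tip axis, protected from pruning.
    Exact on trees (double sweep); a good heuristic if cycles exist."""
    if skel.n_nodes == 0:
        return set()
    comps = sorted(nx.connected_components(skel.graph), key=len, reverse=True)
    g = skel.graph.subgraph(comps[0])

    def far(src):
        dist = {src: 0.0}
        prev = {src: None}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + float(np.linalg.norm(skel.coords[u] - skel.coords[v]))
                    prev[v] = u
                    stack.append(v)
        end = max(dist, key=lambda n: (dist[n], skel._node_key(n)))
        return end, prev

    a, _ = far(next(iter(g.nodes)))
    b, prev = far(a)
    path = set()
    cur = b
    while cur is not None:
        path.add(cur)
        cur = prev[cur]
    return path


def prune(
    raw: CurveSkeleton,
    min_branch_len: int = 10,
    min_branch_straightness: float = 0.5,
) -> CurveSkeleton:
    """Remove spurious terminal branches until a fixed point.

    A terminal branch (one free endpoint) is deleted when it spans fewer
    than ``min_branch_len`` voxels or its end-to-end / along-path length
    ratio falls below ``min_branch_straightness``.  The longest
    root-to-tip path is never removed; junction nodes that drop to
    degree 2 merge into their neighbours on the next pass.  If pruning
    would delete everything, the longest path is kept with a warning.
    """
    skel = raw
    protected = _longest_path_nodes(skel)
    while True:
        if skel.n_nodes == 0:
            return skel
        deg = dict(skel.graph.degree())
        removed: set[int] = set()
        for path in skel.branches():
            end_a, end_b = path[0], path[-1]
            da, db = deg.get(end_a, 0), deg.get(end_b, 0)
            if da != 1 and db != 1:
                continue  # internal branch between junctions
            if da == 1 and db == 1:
                continue  # a whole isolated curve; never prune
            free_end = end_a if da == 1 else end_b
            spur = path[:-1] if free_end == end_a else path[1:]
            if set(spur) <= protected:
                continue
            n_vox = len(path)
            chord = float(np.linalg.norm(skel.coords[end_a] - skel.coords[end_b]))
            along = skel.branch_length_mm(path)
            straightness = chord / along if along > 0 else 1.0
            if n_vox < min_branch_len or straightness < min_branch_straightness:
                removed.update(spur)
        if not removed:
            return skel
        keep = set(range(skel.n_nodes)) - removed
        if not keep:
            warnings.warn("pruning would remove all nodes; keeping longest path")
            keep = protected
        skel = skel.subset(keep)
        # node ids changed; recompute protection in the new labelling
        protected = _longest_path_nodes(skel)


def connect_components(skel: CurveSkeleton) -> CurveSkeleton:
    """Join disconnected skeleton components into one.

    Greedy: the nearest node pair between the main (largest) component
    and each minor component is bridged with interpolated connector
    nodes (flagged synthetic) spaced at the voxel size.
    """
    if skel.n_nodes == 0 or skel.n_components() <= 1:
        return skel
    indices = [tuple(v) for v in skel.indices]
    coords = list(map(np.asarray, skel.coords))
    synthetic = list(skel.synthetic)
    g = skel.graph.copy()

    while True:
        comps = sorted(
            nx.connected_components(g),
            key=lambda c: (-len(c), min(skel._node_key(n) if n < skel.n_nodes else (1 << 30, 0, 0, n) for n in c)),
        )
        if len(comps) == 1:
            break
        main = comps[0]
        main_ids = sorted(main)
        main_pts = np.array([coords[i] for i in main_ids])
        tree = cKDTree(main_pts)
        # nearest minor component to the main one
        best = None
        for comp in comps[1:]:
            ids = sorted(comp)
            pts = np.array([coords[i] for i in ids])
            d, j = tree.query(pts)
            k = int(np.argmin(d))
            cand = (float(d[k]), ids[k], main_ids[int(j[k])])
            if best is None or cand[0] < best[0]:
                best = cand
        _, a, b = best
        pa, pb = coords[a], coords[b]
        gap = float(np.linalg.norm(pb - pa))
        n_new = max(int(np.floor(gap / max(skel.voxel_size, 1e-9))) - 1, 0)
        prev = a
        for t in np.linspace(0, 1, n_new + 2)[1:-1]:
            p = pa + t * (pb - pa)
            nid = len(coords)
            coords.append(p)
            origin = np.array([-skel.side / 2.0, -skel.side / 2.0, 0.0])
            vidx = np.round((p - origin) / max(skel.voxel_size, 1e-9) - 0.5).astype(int)
            indices.append(tuple(vidx))
            synthetic.append(True)
            g.add_node(nid)
            g.add_edge(prev, nid)
            prev = nid
        g.add_edge(prev, b)

    return CurveSkeleton(
        indices=np.asarray(indices, dtype=int).reshape(-1, 3),
        coords=np.asarray(coords, dtype=float).reshape(-1, 3),
        graph=g,
        synthetic=np.asarray(synthetic, dtype=bool),
        voxel_size=skel.voxel_size,
        resolution=skel.resolution,
        side=skel.side,
    )


@dataclass
class StemBase:
    node: int | None
    confidence: float
    ok: bool
    reason: str | None = None


def _branch_of_endpoint(skel: CurveSkeleton, endpoint: int) -> list[int]:
    for path in skel.branches():
        if path[0] == endpoint:
            return path
        if path[-1] == endpoint:
            return path[::-1]
    return [endpoint]


def _vertical_fraction(skel: CurveSkeleton, path: list[int], tol_deg: float, window: int = 5) -> float:
    """Fraction of windowed local directions along a path within
    ``tol_deg`` of vertical."""
    c = skel.coords[path]
    if len(c) < 2:
        return 0.0
    steps = []
    for i in range(len(c) - 1):
        j = min(i + window, len(c) - 1)
        d = c[j] - c[i]
        n = np.linalg.norm(d)
        if n > 0:
            steps.append(abs(d[2]) / n)
    if not steps:
        return 0.0
    cos_tol = np.cos(np.deg2rad(tol_deg))
    return float(np.mean(np.asarray(steps) >= cos_tol))


def find_stem_base(
    skel: CurveSkeleton,
    vertical_tol_deg: float = 30.0,
    min_confidence: float = 0.5,
    height_band_frac: float = 0.15,
) -> StemBase:
    """Locate the soil-stem junction.

    Candidate nodes are skeleton endpoints whose incident branch's
    principal direction lies within ``vertical_tol_deg`` of vertical.
    Among candidates in the lowest height band (lowest endpoint plus
    ``height_band_frac`` of the plant's height extent) the most vertical
    branch wins, ties broken by lower height then (z, y, x) index.
    Confidence is the fraction of the basal branch locally within the
    verticality tolerance; below ``min_confidence`` the reconstruction
    is flagged with the no-stem-junction failure class.
    """
    if skel.n_nodes == 0:
        return StemBase(None, 0.0, False, REASON_NO_STEM_JUNCTION)
    eps = skel.endpoints()
    if not eps:
        return StemBase(None, 0.0, False, REASON_NO_STEM_JUNCTION)
    cos_tol = np.cos(np.deg2rad(vertical_tol_deg))
    cands = []
    for e in eps:
        path = _branch_of_endpoint(skel, e)
        c = skel.coords[path]
        if len(c) < 2:
            continue
        cc = c - c.mean(axis=0)
        _, _, vt = np.linalg.svd(cc, full_matrices=False)
        v1 = vt[0]
        vert = abs(v1[2])  # |cos| of angle to vertical
        if vert >= cos_tol:
            conf = _vertical_fraction(skel, path, vertical_tol_deg)
            cands.append((e, skel.coords[e][2], vert, conf))
    if not cands:
        return StemBase(None, 0.0, False, REASON_NO_STEM_JUNCTION)
    zmin = min(z for _, z, _, _ in cands)
    zext = float(skel.coords[:, 2].max() - skel.coords[:, 2].min())
    band = [c for c in cands if c[1] <= zmin + height_band_frac * max(zext, 1e-9)]
    band.sort(key=lambda c: (-c[2], c[1], skel._node_key(c[0])))
    node, _, _, conf = band[0]
    if conf < min_confidence:
        return StemBase(node, conf, False, REASON_NO_STEM_JUNCTION)
    return StemBase(node, conf, True)
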