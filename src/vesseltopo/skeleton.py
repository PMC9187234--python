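"""Binary 3D skeleton stacks and their conversion to spatial vessel graphs.

Input stacks are thin (1-voxel-wide) skeletons of segmented vasculature,
stored as TIFF stacks or NIfTI volumes with any integer dtype; every nonzero
voxel is foreground. Voxel arrays are indexed ``(z, y, x)`` and carry an
anisotropic spacing ``(dz, dy, dx)`` in micrometers per voxel.

Extraction uses 26-connectivity. Two cleanup steps keep the extracted graph
faithful to the skeleton's topology:

* *triangle pruning* — 26-adjacency of rasterized lines creates spurious
  3-cycles at corners (a voxel and its second-next neighbor touching
  diagonally); the longest edge of every such triangle is removed, which
  preserves connectivity and removes exactly the artifactual loops;
* *junction clustering* — mutually adjacent branching voxels (>= 3 skeleton
  neighbors) are collapsed into a single branching node at their centroid,
  avoiding spurious micro-segments at thick junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .network import VesselNetwork, build_network

logger = logging.getLogger(__name__)

# all 26 neighbor offsets in (z, y, x) index space
_OFFSETS = np.array([(dz, dy, dx)
                     for dz in (-1, 0, 1)
                     for dy in (-1, 0, 1)
                     for dx in (-1, 0, 1)
                     if (dz, dy, dx) != (0, 0, 0)], dtype=int)


@dataclass
class VoxelSkeleton:
    """A set of foreground voxels with shape and anisotropic spacing."""

    shape: Tuple[int, int, int]          # (nz, ny, nx)
    voxels: np.ndarray                   # (n, 3) int indices (z, y, x)
    spacing: Tuple[float, float, float]  # (dz, dy, dx) in um/voxel

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError("voxels must be an (n, 3) index array")
        if len(self.voxels) == 0:
            raise ValueError("empty skeleton: no foreground voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if (self.voxels.min() < 0
                or (self.voxels >= np.asarray(self.shape)).any()):
            raise ValueError("foreground voxel outside the stated shape")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.shape, dtype=np.uint8)
        arr[tuple(self.voxels.T)] = 1
        return arr


def read_skeleton_stack(path, spacing) -> VoxelSkeleton:
    """Read a binary 3D stack (TIFF or NIfTI); any nonzero voxel is foreground.

    NIfTI volumes are stored (x, y, z) and are transposed to the (z, y, x)
    convention used here. ``spacing`` is ``(dz, dy, dx)`` in micrometers.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).dataobj)
        arr = arr.T  # (x, y, z) -> (z, y, x)
    else:
        import tifffile

        arr = tifffile.imread(str(path))
    arr = np.squeeze(arr)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D stack, got shape {arr.shape}")
    voxels = np.argwhere(arr != 0)
    if len(voxels) == 0:
        raise ValueError("empty skeleton: no foreground voxels")
    return VoxelSkeleton(shape=tuple(arr.shape), voxels=voxels,
                         spacing=tuple(float(s) for s in spacing))


# ---------------------------------------------------------------------------
# graph extraction


def _voxel_graph(skel: VoxelSkeleton):
    """26-adjacency graph over foreground voxels (as index tuples)."""
    vox = [tuple(v) for v in skel.voxels]
    vset = set(vox)
    adj: Dict[tuple, set] = {v: set() for v in vox}
    for v in vox:
        vz, vy, vx = v
        for dz, dy, dx in _OFFSETS:
            w = (vz + dz, vy + dy, vx + dx)
            if w in vset:
                adj[v].add(w)
    return adj


def _prune_triangles(adj: Dict[tuple, set]) -> None:
    """Remove the longest edge of every 3-cycle, in place.

    Edges are visited in descending squared index length (1, 2 or 3), ties
    broken lexicographically, so the diagonal shortcut of a corner is always
    the edge removed. Removal never disconnects (the two shorter edges
    remain) and never creates new triangles, so one pass suffices.
    """
    edges = []
    for u in adj:
        for v in adj[u]:
            if u < v:
                d2 = sum((a - b) ** 2 for a, b in zip(u, v))
                edges.append((-d2, u, v))
    for _, u, v in sorted(edges):
        if v in adj[u] and adj[u] & adj[v]:
            adj[u].discard(v)
            adj[v].discard(u)


def _cluster_branching(adj: Dict[tuple, set]):
    """Group mutually adjacent branching voxels; return voxel -> group id and
    group id -> member list, ids assigned by smallest member voxel."""
    branching = {v for v in adj if len(adj[v]) >= 3}
    parent = {v: v for v in branching}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for v in branching:
        for w in adj[v]:
            if w in branching:
                ra, rb = find(v), find(w)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: Dict[tuple, List[tuple]] = {}
    for v in branching:
        groups.setdefault(find(v), []).append(v)
    label: Dict[tuple, tuple] = {}
    for root, members in groups.items():
        anchor = min(members)
        for v in members:
            label[v] = anchor
    return label, groups


def extract_network(skel: VoxelSkeleton) -> VesselNetwork:
    """Extract the spatial vessel graph from a thin voxel skeleton.

    Node positions are voxel centers scaled by the spacing (micrometers,
    (x, y, z) order). Voxels with >= 3 skeleton neighbors become branching
    nodes (clusters collapse to their centroid), 1 neighbor endpoints, 2
    interior. Segments are maximal degree-2 paths; isolated voxels become
    single-node components.
    """
    adj = _voxel_graph(skel)
    n_thick = sum(1 for v in adj if len(adj[v]) > 8)
    if n_thick:
        logger.warning(
            "skeleton looks thick: %d voxels with >8 neighbors", n_thick)
    _prune_triangles(adj)
    label, _groups = _cluster_branching(adj)

    def group_of(v):
        return label.get(v, v)

    # quotient graph over groups
    qadj: Dict[tuple, set] = {}
    members: Dict[tuple, List[tuple]] = {}
    for v in adj:
        g = group_of(v)
        members.setdefault(g, []).append(v)
        qadj.setdefault(g, set())
    for v in adj:
        for w in adj[v]:
            gv, gw = group_of(v), group_of(w)
            if gv != gw:
                qadj[gv].add(gw)
                qadj[gw].add(gv)

    # collapsing a junction can leave triangles (two line voxels adjacent to
    # each other and to the same cluster); in each one drop the edge with
    # the fewest cluster endpoints so arms stay attached to the junction
    def is_cluster(g):
        return len(members.get(g, ())) > 1

    changed = True
    while changed:
        changed = False
        for g in sorted(qadj):
            for h in sorted(qadj[g]):
                if g < h and qadj[g] & qadj[h]:
                    c = min(qadj[g] & qadj[h])
                    tri = [(g, h), tuple(sorted((g, c))), tuple(sorted((h, c)))]
                    drop = min(tri, key=lambda e: (is_cluster(e[0]) +
                                                   is_cluster(e[1]), e))
                    qadj[drop[0]].discard(drop[1])
                    qadj[drop[1]].discard(drop[0])
                    changed = True
                    break
            if changed:
                break

    dz, dy, dx = skel.spacing
    ids = {g: i for i, g in enumerate(sorted(qadj))}
    positions = {}
    for g, i in ids.items():
        pts = np.asarray(members[g], dtype=float)  # (m, 3) in (z, y, x)
        czyx = pts.mean(axis=0)
        positions[i] = np.array([czyx[2] * dx, czyx[1] * dy, czyx[0] * dz])
    edges = sorted({tuple(sorted((ids[g], ids[h])))
                    for g in qadj for h in qadj[g]})
    return build_network(positions, edges)
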