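"""Spatial vessel networks and their segment decomposition.

A vessel network is a spatial graph: nodes embedded in 3D (coordinates in
micrometers) joined by edges that represent pieces of blood vessel. The edge
set is partitioned into *segments*: maximal vessel paths running between
branching points (degree >= 3) and/or endpoints (degree 1) through degree-2
interior nodes. Segments are the unit by which the topological descriptors
are normalized, so the decomposition is maintained as an invariant of the
data structure rather than recomputed ad hoc.

Node kinds follow graph degree: ``branching`` for degree >= 3, ``endpoint``
for degree 1 (and isolated degree-0 nodes), ``interior`` for degree 2. A
component that is a pure cycle (every node degree 2) is represented as one
closed segment whose start/end node is the smallest node id in the cycle and
keeps kind ``interior``.

Coordinates are real-valued micrometers in (x, y, z) order; all distances
are Euclidean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("branching", "interior", "endpoint")


@dataclass
class Node:
    """A vessel-network node at a 3D position (micrometers)."""

    id: int
    xyz: np.ndarray
    kind: str
    diameter: Optional[float] = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"node {self.id}: xyz must be a 3-vector")
        if self.kind not in KINDS:
            raise ValueError(f"node {self.id}: unknown kind {self.kind!r}")


def _ekey(u: int, v: int) -> Tuple[int, int]:
    return (u, v) if u <= v else (v, u)


@dataclass
class VesselNetwork:
    """Spatial vessel graph with an explicit segment decomposition.

    Attributes
    ----------
    nodes:
        Mapping node id -> :class:`Node`.
    edges:
        Sorted list of unordered node-id pairs ``(u, v)`` with ``u < v``.
    segments:
        List of node-id paths. Every edge belongs to exactly one segment.
    """

    nodes: Dict[int, Node]
    edges: List[Tuple[int, int]] = field(default_factory=list)
    segments: List[List[int]] = field(default_factory=list)

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def node_ids(self) -> List[int]:
        return sorted(self.nodes)

    def coords(self, ids: Optional[Sequence[int]] = None) -> np.ndarray:
        """Node coordinates as an ``(n, 3)`` array, in sorted-id order."""
        ids = self.node_ids() if ids is None else list(ids)
        return np.array([self.nodes[i].xyz for i in ids], dtype=float)

    def neighbors(self) -> Dict[int, List[int]]:
        adj: Dict[int, List[int]] = {i: [] for i in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def degree(self) -> Dict[int, int]:
        return {i: len(vs) for i, vs in self.neighbors().items()}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, node in self.nodes.items():
            g.add_node(i, x=node.xyz[0], y=node.xyz[1], z=node.xyz[2],
                       kind=node.kind,
                       **({"diameter": node.diameter}
                          if node.diameter is not None else {}))
        g.add_edges_from(self.edges)
        return g

    @property
    def n_components(self) -> int:
        import networkx as nx

        return nx.number_connected_components(self.to_networkx())

    @property
    def cycle_rank(self) -> int:
        """Number of independent loops, E - V + C."""
        return self.n_edges - self.n_nodes + self.n_components

    def edge_length(self, u: int, v: int) -> float:
        return float(np.linalg.norm(self.nodes[u].xyz - self.nodes[v].xyz))

    def segment_length(self, path: Sequence[int]) -> float:
        return float(sum(self.edge_length(a, b) for a, b in zip(path, path[1:])))

    def segment_coords(self, path: Sequence[int]) -> np.ndarray:
        return np.array([self.nodes[i].xyz for i in path], dtype=float)

    def total_length(self) -> float:
        return float(sum(self.edge_length(u, v) for u, v in self.edges))

    # ------------------------------------------------------------- transforms
    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            nodes={i: replace(n, xyz=n.xyz.copy()) for i, n in self.nodes.items()},
            edges=list(self.edges),
            segments=[list(s) for s in self.segments],
        )

    def translate(self, vec) -> "VesselNetwork":
        vec = np.asarray(vec, dtype=float)
        out = self.copy()
        for n in out.nodes.values():
            n.xyz = n.xyz + vec
        return out

    def transform(self, matrix) -> "VesselNetwork":
        """Apply a 3x3 linear map (e.g. a rotation) to all coordinates."""
        m = np.asarray(matrix, dtype=float)
        out = self.copy()
        for n in out.nodes.values():
            n.xyz = m @ n.xyz
        return out

    # ------------------------------------------------------------- invariants
    def validate(self) -> None:
        """Assert the structural invariants; raise ``ValueError`` on failure."""
        deg = self.degree()
        for i, node in self.nodes.items():
            d = deg[i]
            expected = ("branching" if d >= 3 else
                        "interior" if d == 2 else "endpoint")
            if node.kind != expected:
                raise ValueError(
                    f"node {i}: kind {node.kind!r} inconsistent with degree {d}")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop edge ({u},{v}) is not allowed")
            if self.edge_length(u, v) <= 0:
                raise ValueError(f"edge ({u},{v}) has non-positive length")
        seen: Dict[Tuple[int, int], int] = {}
        for si, path in enumerate(self.segments):
            if len(path) < 2:
                raise ValueError(f"segment {si} has fewer than 2 nodes")
            closed = path[0] == path[-1]
            interior = path[1:-1]
            if len(set(interior)) != len(interior) or (not closed and
                                                       len(set(path)) != len(path)):
                raise ValueError(f"segment {si} is not a simple path")
            for a, b in zip(path, path[1:]):
                key = _ekey(a, b)
                if key in seen:
                    raise ValueError(
                        f"edge {key} appears in segments {seen[key]} and {si}")
                seen[key] = si
        if set(seen) != set(self.edges):
            raise ValueError("segments do not partition the edge set")


# ---------------------------------------------------------------------------
# construction


def _decompose(adj: Mapping[int, Sequence[int]]) -> List[List[int]]:
    """Trace maximal degree-2 paths between terminals; cycles become closed
    segments anchored at their smallest node id."""
    deg = {u: len(vs) for u, vs in adj.items()}
    visited: set = set()
    segments: List[List[int]] = []

    def walk(start: int, first: int) -> List[int]:
        path = [start, first]
        visited.add(_ekey(start, first))
        while deg[path[-1]] == 2 and path[-1] != start:
            a, b = sorted(adj[path[-1]])
            nxt = b if a == path[-2] else a
            visited.add(_ekey(path[-1], nxt))
            path.append(nxt)
        return path

    for t in sorted(u for u in adj if deg[u] != 2):
        for nb in sorted(adj[t]):
            if _ekey(t, nb) not in visited:
                segments.append(walk(t, nb))
    # remaining edges belong to pure cycles (all nodes degree 2)
    for u in sorted(adj):
        for nb in sorted(adj[u]):
            if _ekey(u, nb) not in visited:
                segments.append(walk(u, nb))
    return segments


def build_network(
    positions: Mapping[int, Sequence[float]],
    edges: Iterable[Tuple[int, int]],
    diameters: Optional[Mapping[int, float]] = None,
) -> VesselNetwork:
    """Build a :class:`VesselNetwork` from positions and an edge list.

    Node kinds are derived from graph degree and the segment decomposition is
    traced deterministically (terminals and their neighbors visited in
    ascending id order).
    """
    diameters = diameters or {}
    edge_set = sorted({_ekey(u, v) for u, v in edges})
    for u, v in edge_set:
        if u == v:
            raise ValueError(f"self-loop edge ({u},{v}) is not allowed")
        if u not in positions or v not in positions:
            raise ValueError(f"edge ({u},{v}) references unknown node")
    adj: Dict[int, List[int]] = {i: [] for i in positions}
    for u, v in edge_set:
        adj[u].append(v)
        adj[v].append(u)
    nodes = {}
    for i in positions:
        d = len(adj[i])
        kind = "branching" if d >= 3 else "interior" if d == 2 else "endpoint"
        if d == 0:
            logger.info("node %d is an isolated single-node component", i)
        nodes[i] = Node(id=i, xyz=np.asarray(positions[i], dtype=float),
                        kind=kind, diameter=diameters.get(i))
    net = VesselNetwork(nodes=nodes, edges=edge_set,
                        segments=_decompose(adj))
    net.validate()
    return net


def renumber(net: VesselNetwork) -> VesselNetwork:
    """Relabel node ids to 0..n-1 in sorted order."""
    mapping = {old: new for new, old in enumerate(net.node_ids())}
    return build_network(
        {mapping[i]: n.xyz for i, n in net.nodes.items()},
        [(mapping[u], mapping[v]) for u, v in net.edges],
        {mapping[i]: n.diameter for i, n in net.nodes.items()
         if n.diameter is not None},
    )


def disjoint_union(a: VesselNetwork, b: VesselNetwork) -> VesselNetwork:
    """Disjoint union of two networks; ids of ``b`` are shifted."""
    offset = (max(a.nodes) + 1) if a.nodes else 0
    positions = {i: n.xyz for i, n in a.nodes.items()}
    diam = {i: n.diameter for i, n in a.nodes.items() if n.diameter is not None}
    edges = list(a.edges)
    for i, n in b.nodes.items():
        positions[i + offset] = n.xyz
        if n.diameter is not None:
            diam[i + offset] = n.diameter
    edges += [(u + offset, v + offset) for u, v in b.edges]
    return build_network(positions, edges, diam)


# ---------------------------------------------------------------------------
# preprocessing


def rescale_z(net: VesselNetwork, factor: float) -> VesselNetwork:
    """Multiply every z coordinate by ``factor`` (anisotropy correction).

    The standard correction for the difference in resolution between the
    z axis and the x-y plane of intravital stacks uses factor 0.835.
    """
    if factor <= 0:
        raise ValueError("z-rescale factor must be positive")
    out = net.copy()
    for n in out.nodes.values():
        n.xyz[2] *= factor
    return out


def _orient(path: List[int]) -> List[int]:
    """Canonical orientation: open paths run from the smaller-id terminus;
    closed paths keep their anchor but take the smaller-id first step."""
    if path[0] == path[-1]:
        if len(path) > 3 and path[1] > path[-2]:
            return path[::-1]
        return path
    return path if path[0] < path[-1] else path[::-1]


def subsample_branches(net: VesselNetwork, k: int) -> VesselNetwork:
    """Keep all termini and every k-th interior node of each segment.

    Interior nodes are counted 1-based from the lower-id terminus; node ``i``
    is retained iff ``i % k == 0``. Connectivity and cycle rank are preserved
    exactly: a segment whose collapse would create a parallel edge keeps its
    middle interior node, and closed segments always keep at least two
    interior nodes.
    """
    if k < 1:
        raise ValueError("subsampling step k must be >= 1")
    if k == 1:
        return net.copy()
    positions: Dict[int, np.ndarray] = {}
    diam: Dict[int, float] = {}
    new_edges: set = set()
    for raw in net.segments:
        path = _orient(list(raw))
        interior = path[1:-1]
        kept = [interior[i - 1] for i in range(1, len(interior) + 1) if i % k == 0]
        closed = path[0] == path[-1]
        if closed and len(kept) < 2:
            # a closed segment must stay a simple cycle of length >= 3
            kept = sorted({interior[0], interior[len(interior) // 2]},
                          key=interior.index)
        newpath = [path[0]] + kept + [path[-1]]
        pairs = [_ekey(a, b) for a, b in zip(newpath, newpath[1:])]
        if len(set(pairs)) != len(pairs) or any(p in new_edges for p in pairs):
            # collapsing duplicated an edge: retain the middle interior node
            mid = interior[len(interior) // 2]
            if mid not in kept:
                kept = sorted(set(kept) | {mid}, key=interior.index)
                newpath = [path[0]] + kept + [path[-1]]
                pairs = [_ekey(a, b) for a, b in zip(newpath, newpath[1:])]
        for i in newpath:
            positions[i] = net.nodes[i].xyz
            if net.nodes[i].diameter is not None:
                diam[i] = net.nodes[i].diameter
        new_edges.update(pairs)
    adj = net.neighbors()
    for i, node in net.nodes.items():  # isolated nodes survive subsampling
        if not adj[i]:
            positions[i] = node.xyz
    return build_network(positions, new_edges, diam)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class NetworkSummary:
    """Standard per-network measures (counts, lengths, diameters)."""

    n_segments: int
    n_branching_points: int
    n_components: int
    total_length: float
    mean_segment_length: float
    max_segment_length: float
    mean_diameter: Optional[float]
    max_diameter: Optional[float]
    length_to_diameter: Optional[float]
    segment_table: pd.DataFrame

    def to_dict(self) -> Dict[str, Optional[float]]:
        return {
            "n_segments": self.n_segments,
            "n_branching_points": self.n_branching_points,
            "n_components": self.n_components,
            "total_length": self.total_length,
            "mean_segment_length": self.mean_segment_length,
            "max_segment_length": self.max_segment_length,
            "mean_diameter": self.mean_diameter,
            "max_diameter": self.max_diameter,
            "length_to_diameter": self.length_to_diameter,
        }


def summarize(net: VesselNetwork) -> NetworkSummary:
    """Compute counts, segment lengths and (when available) diameters.

    The length-to-diameter ratio is the unweighted mean over segments of
    segment length divided by the segment's mean node diameter; it is
    reported absent (``None``) when any diameter is missing.
    """
    if not net.nodes:
        raise ValueError("cannot summarize an empty network")
    rows = []
    for si, path in enumerate(net.segments):
        length = net.segment_length(path)
        diams = [net.nodes[i].diameter for i in path]
        mean_d = (float(np.mean(diams)) if all(d is not None for d in diams)
                  and diams else None)
        rows.append({"segment": si, "n_nodes": len(path), "length": length,
                     "mean_diameter": mean_d})
    table = pd.DataFrame(rows, columns=["segment", "n_nodes", "length",
                                        "mean_diameter"])
    lengths = table["length"].to_numpy() if len(table) else np.array([0.0])
    have_diam = len(table) > 0 and table["mean_diameter"].notna().all()
    all_d = [n.diameter for n in net.nodes.values()]
    ld = (float(np.mean(table["length"] / table["mean_diameter"]))
          if have_diam else None)
    return NetworkSummary(
        n_segments=net.n_segments,
        n_branching_points=sum(1 for n in net.nodes.values()
                               if n.kind == "branching"),
        n_components=net.n_components,
        total_length=net.total_length(),
        mean_segment_length=float(lengths.mean()) if net.n_segments else 0.0,
        max_segment_length=float(lengths.max()) if net.n_segments else 0.0,
        mean_diameter=(float(np.mean([d for d in all_d if d is not None]))
                       if have_diam else None),
        max_diameter=(float(np.max([d for d in all_d if d is not None]))
                      if have_diam else None),
        length_to_diameter=ld,
        segment_table=table,
    )


# ---------------------------------------------------------------------------
# serialization (JSON dialect documented in docs/format.md)


def write_network(net: VesselNetwork, path) -> None:
    doc = {
        "nodes": [
            {"id": i, "xyz": [float(c) for c in n.xyz], "kind": n.kind,
             **({"diameter": float(n.diameter)}
                if n.diameter is not None else {})}
            for i, n in sorted(net.nodes.items())
        ],
        "edges": [[int(u), int(v)] for u, v in net.edges],
        "segments": [[int(i) for i in s] for s in net.segments],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_network(path) -> VesselNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("nodes", "edges", "segments"):
        if key not in doc:
            raise ValueError(f"network file is missing key '{key}'")
    positions, diam = {}, {}
    kinds = {}
    for idx, entry in enumerate(doc["nodes"]):
        for key in ("id", "xyz", "kind"):
            if key not in entry:
                raise ValueError(f"nodes[{idx}] is missing key '{key}'")
        i = int(entry["id"])
        positions[i] = entry["xyz"]
        kinds[i] = entry["kind"]
        if "diameter" in entry:
            diam[i] = float(entry["diameter"])
    net = VesselNetwork(
        nodes={i: Node(id=i, xyz=positions[i], kind=kinds[i],
                       diameter=diam.get(i)) for i in positions},
        edges=sorted(_ekey(int(u), int(v)) for u, v in doc["edges"]),
        segments=[[int(i) for i in s] for s in doc["segments"]],
    )
    net.validate()
    return net


def write_graphml(net: VesselNetwork, path) -> None:
    """GraphML export with positions, kinds and diameters as attributes.

    GraphML has no natural home for the segment decomposition; the JSON
    dialect is the lossless format.
    """
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)
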