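"""Multiscale lenses on vessel data: radial and alpha-complex filtrations.

Two filtrations feed the persistence engine:

* the **radial filtration** grows a sphere from the tumor center (the center
  of mass of the network nodes) in ``n_steps`` uniform radius increments;
  at each step all nodes within the radius enter, and an edge enters as soon
  as both its endpoints are inside. It contains only vertices and edges —
  triangles are never filled — so its homology lives in dimensions 0 and 1;

* the **alpha-complex filtration** filters the Delaunay triangulation of the
  3D node cloud by squared circumradius: a simplex whose circumsphere is
  empty of other vertices enters at its own squared circumradius, otherwise
  at the smallest value of a higher-dimensional coface. Its dimension-2
  classes are the avascular voids.

Radial filtration values are stored as integer step indices of the uniform
grid ``{r_max * s / n_steps : s = 1..n_steps}`` so ties between steps are
exact; real-valued radii are recovered on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .network import VesselNetwork

_SNAP = 1e-9  # relative tolerance when snapping distances to grid radii


def center_of_mass(net: VesselNetwork) -> np.ndarray:
    """Unweighted arithmetic mean of all node coordinates (tumor-center proxy)."""
    if not net.nodes:
        raise ValueError("cannot take the center of mass of an empty network")
    return net.coords().mean(axis=0)


@dataclass
class GraphFiltration:
    """Radial filtration of a vessel graph: node/edge entry radii on a grid."""

    network: VesselNetwork
    center: np.ndarray
    n_steps: int
    r_max: float
    node_steps: Dict[int, int]  # node id -> step index in 1..n_steps

    @property
    def end_value(self) -> float:
        return self.r_max

    def step_value(self, s: int) -> float:
        return self.r_max * s / self.n_steps

    def node_value(self, i: int) -> float:
        return self.step_value(self.node_steps[i])

    def edge_step(self, u: int, v: int) -> int:
        # an edge enters only when both endpoints are inside the sphere
        return max(self.node_steps[u], self.node_steps[v])

    def edge_value(self, u: int, v: int) -> float:
        return self.step_value(self.edge_step(u, v))

    def validate(self) -> None:
        for s in self.node_steps.values():
            if not (1 <= s <= self.n_steps):
                raise ValueError("node step outside the filtration grid")
        for u, v in self.network.edges:
            if self.edge_step(u, v) < max(self.node_steps[u],
                                          self.node_steps[v]):
                raise ValueError("edge enters before one of its endpoints")


def radial_filtration(net: VesselNetwork,
                      center: Optional[Sequence[float]] = None,
                      n_steps: int = 500) -> GraphFiltration:
    """Build the radial filtration of ``net`` around ``center``.

    ``r_max`` is the maximal node distance to the center, divided into
    ``n_steps`` uniform radii. Each node snaps **up** to the smallest grid
    radius >= its distance (a node exactly on a grid radius enters at that
    radius); each edge enters at the larger of its endpoint radii.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not net.nodes:
        raise ValueError("cannot filter an empty network")
    c = center_of_mass(net) if center is None else np.asarray(center, float)
    ids = net.node_ids()
    dist = np.linalg.norm(net.coords() - c, axis=1)
    r_max = float(dist.max())
    if r_max == 0.0:
        steps = {i: 1 for i in ids}
        return GraphFiltration(net, c, n_steps, 0.0, steps)
    raw = n_steps * dist / r_max
    snapped = np.ceil(raw - _SNAP * n_steps).astype(int)
    steps = {i: int(max(1, s)) for i, s in zip(ids, snapped)}
    filt = GraphFiltration(net, c, n_steps, r_max, steps)
    filt.validate()
    return filt


def restrict_to_ball(filt: GraphFiltration, r: float):
    """The subgraph of all nodes/edges with filtration value <= ``r``.

    Returns a ``networkx.Graph``; nested by construction
    (``r1 <= r2`` implies subgraph(r1) is a subgraph of subgraph(r2)).
    """
    import networkx as nx

    if filt.r_max == 0.0:
        s_cut = filt.n_steps
    else:
        s_cut = int(np.floor(filt.n_steps * r / filt.r_max
                             + _SNAP * filt.n_steps))
    g = nx.Graph()
    g.add_nodes_from(i for i, s in filt.node_steps.items() if s <= s_cut)
    g.add_edges_from((u, v) for u, v in filt.network.edges
                     if filt.edge_step(u, v) <= s_cut)
    return g


# ---------------------------------------------------------------------------
# alpha complex


@dataclass
class SimplicialFiltration:
    """Simplices ``(vertex tuple, dimension, value)`` sorted by (value, dim).

    The final complex is the Delaunay triangulation of ``points``; values are
    squared circumradii (alpha squared, in square micrometers).
    """

    points: np.ndarray
    simplices: List[Tuple[Tuple[int, ...], int, float]] = field(
        default_factory=list)

    @property
    def end_value(self) -> float:
        return max(v for _, _, v in self.simplices) if self.simplices else 0.0

    def validate(self) -> None:
        index = {verts: v for verts, _, v in self.simplices}
        prev = (-np.inf, -1)
        for verts, dim, value in self.simplices:
            if len(verts) != dim + 1:
                raise ValueError(f"simplex {verts}: wrong dimension {dim}")
            if (value, dim) < prev:
                raise ValueError("filtration is not sorted by (value, dim)")
            prev = (value, dim)
            if dim > 0:
                for k in range(dim + 1):
                    face = verts[:k] + verts[k + 1:]
                    if index.get(face, np.inf) > value + 1e-9 * (1 + value):
                        raise ValueError(
                            f"face {face} enters after coface {verts}")


def circumsphere(pts: np.ndarray):
    """Circumcenter and squared circumradius of a k-simplex in 3D.

    The center lies in the simplex's affine hull (so for a triangle this is
    the circumcircle of the triangle in its own plane). Returns
    ``(center, r2)`` or ``None`` for numerically degenerate simplices.
    """
    pts = np.asarray(pts, dtype=float)
    p0, d = pts[0], pts[1:] - pts[0]
    m = d @ d.T
    b = 0.5 * np.einsum("ij,ij->i", d, d)
    try:
        lam = np.linalg.solve(m, b)
    except np.linalg.LinAlgError:
        return None
    if not np.allclose(m @ lam, b, rtol=1e-8, atol=1e-12 * (1 + b.max())):
        return None
    center = p0 + lam @ d
    return center, float(np.sum((center - p0) ** 2))


def jitter_points(points: np.ndarray, rel: float = 1e-6,
                  seed: int = 0) -> np.ndarray:
    """Deterministic jitter (``rel`` x bounding-box diagonal) for breaking
    co-spherical degeneracies of lattice-like point sets."""
    pts = np.asarray(points, dtype=float)
    diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    rng = np.random.default_rng(seed)
    return pts + rng.standard_normal(pts.shape) * rel * max(diag, 1.0)


def alpha_filtration(points) -> SimplicialFiltration:
    """Alpha-complex filtration of a 3D point cloud.

    Values are assigned inductively from tetrahedra downwards: a tetrahedron
    always carries its squared circumradius; a triangle or edge carries its
    own squared circumradius when its circumsphere contains no other vertex,
    and otherwise the minimum value of its cofaces (so, e.g., the long edge
    of a slim triangle only enters together with the triangle). Vertices
    enter at 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise ValueError("alpha filtration needs >= 4 points; "
                         "jitter or add points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(
            "degenerate point configuration (coplanar or co-spherical); "
            "apply jitter_points() first") from exc
    if len(tri.coplanar):
        raise ValueError(
            "Delaunay triangulation dropped points (degenerate input); "
            "apply jitter_points() first")

    tets = sorted({tuple(sorted(int(i) for i in s)) for s in tri.simplices})
    triangles: Dict[Tuple[int, ...], List[Tuple[int, ...]]] = {}
    for t in tets:
        for k in range(4):
            triangles.setdefault(t[:k] + t[k + 1:], []).append(t)
    edges: Dict[Tuple[int, ...], List[Tuple[int, ...]]] = {}
    for f in triangles:
        for k in range(3):
            edges.setdefault(f[:k] + f[k + 1:], []).append(f)

    values: Dict[Tuple[int, ...], float] = {}
    scale2 = float(np.sum((pts.max(axis=0) - pts.min(axis=0)) ** 2))

    for t in tets:
        cs = circumsphere(pts[list(t)])
        if cs is None:  # nearly flat tetrahedron: bound by its longest edge
            sub = pts[list(t)]
            d2 = np.max(np.sum((sub[:, None] - sub[None]) ** 2, axis=-1))
            values[t] = float(d2) / 4.0
        else:
            values[t] = cs[1]

    def assign(simplex: Tuple[int, ...], cofaces: List[Tuple[int, ...]]):
        coface_min = min(values[c] for c in cofaces)
        cs = circumsphere(pts[list(simplex)])
        if cs is None:
            values[simplex] = coface_min
            return
        center, r2 = cs
        d2 = np.sum((pts - center) ** 2, axis=1)
        d2[list(simplex)] = np.inf
        empty = not bool(np.any(d2 < r2 - 1e-9 * scale2))
        # clip to the coface minimum so monotonicity is exact
        values[simplex] = min(r2, coface_min) if empty else coface_min

    for f in sorted(triangles):
        assign(f, triangles[f])
    for e in sorted(edges):
        assign(e, edges[e])

    simplices: List[Tuple[Tuple[int, ...], int, float]] = [
        ((i,), 0, 0.0) for i in range(len(pts))]
    simplices += [(e, 1, values[e]) for e in edges]
    simplices += [(f, 2, values[f]) for f in triangles]
    simplices += [(t, 3, values[t]) for t in tets]
    simplices.sort(key=lambda s: (s[2], s[1], s[0]))
    filt = SimplicialFiltration(points=pts, simplices=simplices)
    filt.validate()
    return filt


def write_simplex_list(filt: SimplicialFiltration, path) -> None:
    """Plain-text export: one ``dim v0 [v1 [v2 [v3]]] value`` line per
    simplex, in filtration order (consumable by external PH tools)."""
    with open(path, "w") as fh:
        for verts, dim, value in filt.simplices:
            fh.write(f"{dim} {' '.join(str(v) for v in verts)} {value:.17g}\n")
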