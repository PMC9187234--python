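"""Persistent homology over the two-element field.

Graph filtrations (radial sweep) are handled by a union-find sweep: each node
births a dimension-0 class at its entry radius; when an edge merges two
components the younger one dies (elder rule, ties resolved in favor of the
smaller union-find root id); an edge joining an already-connected pair births
a dimension-1 class that lives to the end of the filtration, since the
radial filtration never fills in triangles. Simplicial filtrations (alpha
complexes) go through standard boundary-matrix column reduction with binary
coefficients, yielding dimensions 0-2.

Conventions: intervals are half-open ``[b, d)``; a feature is alive at its
birth and dead at its death. Essential classes (alive at the end) record the
final filtration value as their death and are flagged ``essential`` so no
information is lost. Zero-persistence bars (born and merged at the same
filtration value) are retained; downstream descriptors may filter them.

``oracle_betti`` is the test oracle: it assembles dense boundary matrices of
the sub-complex at a given value and computes Betti numbers by direct rank
computation, independently of the reduction's pairing logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .filtrations import GraphFiltration, SimplicialFiltration


@dataclass(frozen=True)
class Bar:
    dim: int
    birth: float
    death: float
    essential: bool = False

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class Barcode:
    """Multiset of (dimension, birth, death) intervals from one filtration."""

    bars: List[Bar]
    end_value: float

    def in_dim(self, dim: int) -> List[Bar]:
        return [b for b in self.bars if b.dim == dim]

    def n_bars(self, dim: Optional[int] = None) -> int:
        return len(self.bars if dim is None else self.in_dim(dim))

    def n_essential(self, dim: Optional[int] = None) -> int:
        sel = self.bars if dim is None else self.in_dim(dim)
        return sum(1 for b in sel if b.essential)

    def persistences(self, dim: Optional[int] = None) -> np.ndarray:
        sel = self.bars if dim is None else self.in_dim(dim)
        return np.array([b.persistence for b in sel], dtype=float)

    def births(self, dim: Optional[int] = None) -> np.ndarray:
        sel = self.bars if dim is None else self.in_dim(dim)
        return np.array([b.birth for b in sel], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.dim, b.birth, b.death, b.essential) for b in self.bars],
            columns=["dimension", "birth", "death", "essential"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, end_value: Optional[float] = None) -> "Barcode":
        df = pd.read_csv(path)
        bars = [Bar(int(r.dimension), float(r.birth), float(r.death),
                    bool(r.essential)) for r in df.itertuples()]
        if end_value is None:
            end_value = float(df["death"].max()) if len(df) else 0.0
        return cls(bars=bars, end_value=end_value)


# ---------------------------------------------------------------------------
# graph filtrations: union-find sweep


class _UnionFind:
    def __init__(self):
        self.parent: Dict[int, int] = {}
        self.birth: Dict[int, int] = {}

    def add(self, i: int, birth: int) -> None:
        self.parent[i] = i
        self.birth[i] = birth

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root


def _persist_graph(filt: GraphFiltration) -> Tuple[Barcode, Barcode]:
    net = filt.network
    uf = _UnionFind()
    bars0: List[Bar] = []
    bars1: List[Bar] = []
    events: Dict[int, Tuple[List[int], List[Tuple[int, int]]]] = {}
    for i, s in filt.node_steps.items():
        events.setdefault(s, ([], []))[0].append(i)
    for u, v in net.edges:
        events.setdefault(filt.edge_step(u, v), ([], []))[1].append((u, v))
    end = filt.end_value
    for s in sorted(events):
        nodes, edges = events[s]
        for i in sorted(nodes):
            uf.add(i, s)
        for u, v in sorted(edges):
            ru, rv = uf.find(u), uf.find(v)
            if ru == rv:
                # a loop closes; it can never die (no triangles are filled)
                bars1.append(Bar(1, filt.step_value(s), end, essential=True))
                continue
            # elder rule: the younger component (larger birth) dies;
            # ties broken by the smaller root id surviving
            if (uf.birth[ru], ru) > (uf.birth[rv], rv):
                ru, rv = rv, ru
            bars0.append(Bar(0, filt.step_value(uf.birth[rv]),
                             filt.step_value(s)))
            uf.parent[rv] = ru
    roots = {uf.find(i) for i in filt.node_steps}
    for r in sorted(roots):
        bars0.append(Bar(0, filt.step_value(uf.birth[r]), end, essential=True))
    key = lambda b: (b.birth, b.death, not b.essential)
    return (Barcode(sorted(bars0, key=key), end),
            Barcode(sorted(bars1, key=key), end))


def persist_dim0_graph(filt: GraphFiltration) -> Barcode:
    """Dimension-0 barcode of a radial graph filtration (one bar per node)."""
    return _persist_graph(filt)[0]


def persist_dim1_graph(filt: GraphFiltration) -> Barcode:
    """Dimension-1 barcode: one essential bar per independent loop
    (total count equals E - V + C of the final graph)."""
    return _persist_graph(filt)[1]


def persist_graph(filt: GraphFiltration) -> Tuple[Barcode, Barcode]:
    """Both barcodes of a radial filtration in a single sweep."""
    return _persist_graph(filt)


# ---------------------------------------------------------------------------
# simplicial filtrations: boundary-matrix reduction


def persist_simplicial(filt: SimplicialFiltration,
                       max_dim: int = 2) -> Barcode:
    """Persistent homology of a sorted simplicial filtration, dims 0..max_dim.

    Standard column reduction of the boundary matrix over the two-element
    field, with sparse columns and a pivot cache. Zero-persistence bars are
    retained; essential classes die at the final filtration value.
    """
    filt.validate()
    simplices = filt.simplices
    index = {verts: j for j, (verts, _, _) in enumerate(simplices)}
    end = filt.end_value
    low_to_col: Dict[int, int] = {}
    paired: Dict[int, int] = {}   # creator index -> destroyer index
    columns: Dict[int, set] = {}
    creators: List[int] = []
    for j, (verts, dim, _value) in enumerate(simplices):
        if dim == 0:
            creators.append(j)
            continue
        col = {index[verts[:k] + verts[k + 1:]] for k in range(dim + 1)}
        while col:
            pivot = max(col)
            other = low_to_col.get(pivot)
            if other is None:
                low_to_col[pivot] = j
                columns[j] = col
                paired[pivot] = j
                break
            col ^= columns[other]
        else:
            creators.append(j)
    bars: List[Bar] = []
    for j in creators:
        verts, dim, value = simplices[j]
        if dim > max_dim:
            continue
        if j in paired:
            death = simplices[paired[j]][2]
            bars.append(Bar(dim, value, death))
        else:
            bars.append(Bar(dim, value, end, essential=True))
    bars.sort(key=lambda b: (b.dim, b.birth, b.death, not b.essential))
    return Barcode(bars, end)


# ---------------------------------------------------------------------------
# Betti curves and the brute-force oracle


@dataclass
class BettiCurve:
    grid: np.ndarray
    counts: Dict[int, np.ndarray] = field(default_factory=dict)

    def beta(self, dim: int) -> np.ndarray:
        return self.counts.get(dim,
                               np.zeros(len(self.grid), dtype=int))


def betti_curve(bc: Barcode, grid: Sequence[float],
                dims: Iterable[int] = (0, 1, 2)) -> BettiCurve:
    """Number of bars alive at each grid value: ``birth <= v < death`` under
    the half-open convention; essential bars count through the end."""
    grid = np.asarray(grid, dtype=float)
    counts = {}
    for dim in dims:
        beta = np.zeros(len(grid), dtype=int)
        for b in bc.in_dim(dim):
            alive = (grid >= b.birth) if b.essential else \
                (grid >= b.birth) & (grid < b.death)
            beta += alive
        counts[dim] = beta
    return BettiCurve(grid=grid, counts=counts)


def _gf2_rank(mat: np.ndarray) -> int:
    """Rank of a binary matrix over the two-element field (dense elimination)."""
    a = mat.astype(np.uint8).copy()
    m, n = a.shape
    rank = 0
    for col in range(n):
        pivots = np.nonzero(a[rank:, col])[0]
        if len(pivots) == 0:
            continue
        p = pivots[0] + rank
        if p != rank:
            a[[rank, p]] = a[[p, rank]]
        rows = np.nonzero(a[:, col])[0]
        rows = rows[rows != rank]
        a[rows] ^= a[rank]
        rank += 1
        if rank == m:
            break
    return rank


def oracle_betti(filt: Union[SimplicialFiltration, GraphFiltration],
                 value: float, dim: int) -> int:
    """Brute-force Betti number of the sub-complex at a filtration value.

    For simplicial filtrations, assembles dense boundary matrices and returns
    ``dim ker(boundary_p) - rank(boundary_{p+1})`` by direct rank computation
    over the two-element field. For graph filtrations, counts connected
    components (dim 0) or independent cycles E - V + C (dim 1) of the
    subgraph inside the ball.
    """
    if isinstance(filt, GraphFiltration):
        import networkx as nx

        from .filtrations import restrict_to_ball

        g = restrict_to_ball(filt, value)
        if dim == 0:
            return nx.number_connected_components(g)
        if dim == 1:
            return (g.number_of_edges() - g.number_of_nodes()
                    + nx.number_connected_components(g))
        return 0

    tol = 1e-12 * (1 + abs(value))
    sub = [(verts, d) for verts, d, v in filt.simplices if v <= value + tol]
    by_dim: Dict[int, List[Tuple[int, ...]]] = {}
    for verts, d in sub:
        by_dim.setdefault(d, []).append(verts)

    def boundary(p: int) -> np.ndarray:
        rows = {verts: i for i, verts in enumerate(by_dim.get(p - 1, []))}
        cols = by_dim.get(p, [])
        mat = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for j, verts in enumerate(cols):
            for k in range(p + 1):
                mat[rows[verts[:k] + verts[k + 1:]], j] = 1
        return mat

    n_p = len(by_dim.get(dim, []))
    if n_p == 0:
        return 0
    rank_p = _gf2_rank(boundary(dim)) if dim > 0 else 0
    rank_up = _gf2_rank(boundary(dim + 1))
    return n_p - rank_p - rank_up


def betti_curve_bruteforce(filt: SimplicialFiltration,
                           grid: Optional[Sequence[float]] = None,
                           dims: Iterable[int] = (0, 1, 2)) -> BettiCurve:
    """Betti curves by direct boundary-matrix rank computation.

    Mathematically the same quantity as :func:`oracle_betti` evaluated at
    every grid value, but computed with one incremental elimination pass per
    dimension (columns are appended in filtration order and reduced against
    an echelon basis), so whole-filtration batteries stay fast. Independent
    of the persistence pairing in :func:`persist_simplicial`.
    """
    if grid is None:
        grid = np.unique([v for _, _, v in filt.simplices])
    grid = np.asarray(grid, dtype=float)
    index = {verts: j for j, (verts, _, _) in enumerate(filt.simplices)}
    max_dim = max(d for _, d, _ in filt.simplices)

    # per dimension: counts of simplices and boundary rank at each grid value
    n_at = {d: np.zeros(len(grid), dtype=int) for d in range(max_dim + 1)}
    rank_at = {d: np.zeros(len(grid), dtype=int) for d in range(max_dim + 2)}
    by_dim: Dict[int, List[Tuple[Tuple[int, ...], float]]] = {}
    for verts, d, v in filt.simplices:
        by_dim.setdefault(d, []).append((verts, v))
    for d in range(max_dim + 1):
        vals = np.array([v for _, v in by_dim.get(d, [])])
        n_at[d] = np.searchsorted(np.sort(vals), grid, side="right")
    for d in range(1, max_dim + 1):
        basis: Dict[int, set] = {}  # pivot -> reduced column
        rank_values: List[float] = []
        for verts, v in by_dim.get(d, []):
            col = {index[verts[:k] + verts[k + 1:]] for k in range(d + 1)}
            while col:
                pivot = max(col)
                if pivot not in basis:
                    basis[pivot] = col
                    rank_values.append(v)
                    break
                col = col ^ basis[pivot]
        rank_at[d] = np.searchsorted(np.sort(np.array(rank_values)), grid,
                                     side="right")
    counts = {}
    for dim in dims:
        if dim > max_dim:
            counts[dim] = np.zeros(len(grid), dtype=int)
        else:
            counts[dim] = n_at[dim] - rank_at[dim] - rank_at.get(
                dim + 1, np.zeros(len(grid), dtype=int))
    return BettiCurve(grid=grid, counts=counts)
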