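"""Synthetic vessel networks and point clouds with known ground truth.

Every generator is deterministic given its seed and returns its declared
topology (component count, cycle rank, void count) alongside the object, so
every downstream stage — extraction, filtration, persistence, descriptors,
cohort statistics — can be tested without microscopy data. The fixtures are
geometric, not mechanistic: they emulate the *shapes* real vessel networks
take (straight or coiled vessels, trees with few loops for sprouting-reduced
vasculature, dense grids of loops for sprouting-increased vasculature,
closed shells enclosing avascular cavities) rather than simulating
angiogenesis.

Coordinates are micrometers. Networks place nodes a few micrometers apart,
matching the sampling density of skeletonized microscopy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .network import VesselNetwork, build_network
from .skeleton import VoxelSkeleton

GOLDEN = (1 + 5 ** 0.5) / 2


@dataclass
class GroundTruth:
    """Machine-checkable topology declared by a generator."""

    n_components: int
    cycle_rank: int
    n_segments: Optional[int] = None
    n_voids: Optional[int] = None
    extras: Dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratorSpec:
    """Declarative request for a synthetic instance (drives the CLI)."""

    kind: str
    params: Dict[str, float] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# polyline vessels


def _polyline_network(points: np.ndarray) -> VesselNetwork:
    points = np.asarray(points, dtype=float)
    n = len(points)
    return build_network({i: points[i] for i in range(n)},
                         [(i, i + 1) for i in range(n - 1)])


def make_straight(length: float = 100.0, spacing: float = 2.0,
                  direction=(1.0, 0.0, 0.0), origin=(0.0, 0.0, 0.0)
                  ) -> Tuple[VesselNetwork, GroundTruth]:
    """A straight vessel of ``length`` um sampled every ``spacing`` um."""
    if length <= 0 or spacing <= 0:
        raise ValueError("length and spacing must be positive")
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    n = max(2, int(round(length / spacing)) + 1)
    t = np.linspace(0.0, length, n)
    pts = np.asarray(origin, float) + t[:, None] * d
    return _polyline_network(pts), GroundTruth(1, 0, n_segments=1)


def make_sinusoid(length: float = 200.0, amplitude: float = 10.0,
                  periods: float = 3.0, spacing: float = 2.0
                  ) -> Tuple[VesselNetwork, GroundTruth]:
    """A planar sinusoidal vessel: x runs over ``length``, y oscillates."""
    if min(length, amplitude, periods, spacing) <= 0:
        raise ValueError("all sinusoid parameters must be positive")
    n = max(3, int(round(length / spacing)) + 1)
    x = np.linspace(0.0, length, n)
    y = amplitude * np.sin(2 * np.pi * periods * x / length)
    pts = np.column_stack([x, y, np.zeros_like(x)])
    return _polyline_network(pts), GroundTruth(1, 0, n_segments=1)


def make_helix(turns: float = 4.0, radius: float = 5.0,
               arc_length: float = 300.0, spacing: float = 1.5,
               center=(0.0, 0.0, 0.0)) -> Tuple[VesselNetwork, GroundTruth]:
    """A helical vessel of fixed arc length.

    The coil winds ``turns`` times around the z axis at ``radius`` um; the
    axial extent shrinks as the turn count grows so the total arc length
    stays at ``arc_length``. Raises if the requested turns cannot fit.
    """
    if min(turns, radius, arc_length, spacing) <= 0:
        raise ValueError("all helix parameters must be positive")
    circumference = 2 * np.pi * radius * turns
    if circumference >= arc_length:
        raise ValueError(
            f"{turns} turns of radius {radius} need more than the arc "
            f"length {arc_length}; reduce turns or radius")
    height = math.sqrt(arc_length ** 2 - circumference ** 2)
    n = max(3, int(round(arc_length / spacing)) + 1)
    s = np.linspace(0.0, 1.0, n)
    theta = 2 * np.pi * turns * s
    pts = np.column_stack([radius * np.cos(theta),
                           radius * np.sin(theta),
                           height * (s - 0.5)]) + np.asarray(center, float)
    return _polyline_network(pts), GroundTruth(1, 0, n_segments=1)


def make_random_walk(n_steps: int = 200, step_length: float = 2.0,
                     max_turn_deg: float = 30.0, seed: int = 0
                     ) -> Tuple[VesselNetwork, GroundTruth]:
    """A tortuous vessel as a bounded-turning random walk.

    Fixed step length and a turning angle bounded by ``max_turn_deg`` keep
    path length and chord-length ratio controllable.
    """
    if n_steps < 1 or step_length <= 0 or max_turn_deg < 0:
        raise ValueError("invalid random-walk parameters")
    rng = np.random.default_rng(seed)
    direction = np.array([1.0, 0.0, 0.0])
    pts = [np.zeros(3)]
    for _ in range(n_steps):
        # random small rotation: axis uniform on the sphere, bounded angle
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(0.0, max_turn_deg))
        direction = (direction * np.cos(angle)
                     + np.cross(axis, direction) * np.sin(angle)
                     + axis * np.dot(axis, direction) * (1 - np.cos(angle)))
        direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + step_length * direction)
    return _polyline_network(np.array(pts)), GroundTruth(1, 0, n_segments=1)


# ---------------------------------------------------------------------------
# branched and loopy networks


def make_tree(depth: int = 3, branching: int = 2,
              segment_length: float = 40.0, spacing: float = 5.0
              ) -> Tuple[VesselNetwork, GroundTruth]:
    """A deterministic branching tree (no loops).

    Every internal node spawns ``branching`` children whose directions fan
    out by fixed angles, alternating the fan plane between levels. With
    ``branching == 2`` the root has degree 2, so its two child branches fuse
    into a single segment; the declared segment count accounts for this.
    """
    if depth < 1 or branching < 2 or segment_length <= 0 or spacing <= 0:
        raise ValueError("invalid tree parameters")
    positions: Dict[int, np.ndarray] = {0: np.zeros(3)}
    edges: List[Tuple[int, int]] = []
    counter = [0]

    def new_id() -> int:
        counter[0] += 1
        return counter[0]

    n_interior = max(1, int(round(segment_length / spacing)) - 1)

    def grow(node: int, direction: np.ndarray, level: int) -> None:
        if level > depth:
            return
        spread = np.radians(70.0)
        for c in range(branching):
            frac = (c - (branching - 1) / 2)
            angle = frac * spread / max(1, branching - 1) * 2
            if level % 2 == 1:  # alternate fan plane to stay 3D
                rot = np.array([
                    [np.cos(angle), -np.sin(angle), 0],
                    [np.sin(angle), np.cos(angle), 0],
                    [0, 0, 1.0]])
            else:
                rot = np.array([
                    [np.cos(angle), 0, -np.sin(angle)],
                    [0, 1.0, 0],
                    [np.sin(angle), 0, np.cos(angle)]])
            d = rot @ direction
            d = d / np.linalg.norm(d)
            prev = node
            for k in range(1, n_interior + 2):
                nid = new_id()
                positions[nid] = (positions[node]
                                  + d * segment_length * k / (n_interior + 1))
                edges.append((prev, nid))
                prev = nid
            grow(prev, d, level + 1)

    grow(0, np.array([1.0, 0.0, 0.0]), 1)
    abstract_edges = sum(branching ** lv for lv in range(1, depth + 1))
    n_segments = abstract_edges - (1 if branching == 2 else 0)
    return (build_network(positions, edges),
            GroundTruth(1, 0, n_segments=n_segments))


def make_ring(radius: float = 40.0, n_points: int = 24,
              center=(0.0, 0.0, 0.0)) -> Tuple[VesselNetwork, GroundTruth]:
    """A single closed vessel loop (cycle rank 1, one closed segment)."""
    if radius <= 0 or n_points < 3:
        raise ValueError("ring needs positive radius and >= 3 points")
    theta = 2 * np.pi * np.arange(n_points) / n_points
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                           np.zeros(n_points)]) + np.asarray(center, float)
    edges = [(i, (i + 1) % n_points) for i in range(n_points)]
    return (build_network({i: pts[i] for i in range(n_points)}, edges),
            GroundTruth(1, 1, n_segments=1))


def make_grid(nx_nodes: int = 3, ny_nodes: int = 3, spacing: float = 10.0,
              samples_per_edge: int = 3) -> Tuple[VesselNetwork, GroundTruth]:
    """A planar lattice of vessel loops with cycle rank (nx-1)(ny-1).

    Lattice crossings are the branching points; each lattice edge carries
    ``samples_per_edge`` interior sample nodes. The four lattice corners
    have degree 2, so each corner fuses its two incident paths into one
    segment; the declared segment count is the lattice edge count minus 4.
    Requires nx, ny >= 3 (use :func:`make_ring` for a single cell).
    """
    if nx_nodes < 3 or ny_nodes < 3:
        raise ValueError("grid needs nx, ny >= 3")
    if spacing <= 0 or samples_per_edge < 0:
        raise ValueError("invalid grid parameters")
    positions: Dict[int, np.ndarray] = {}
    lattice: Dict[Tuple[int, int], int] = {}
    counter = [0]

    def nid() -> int:
        counter[0] += 1
        return counter[0] - 1

    for j in range(ny_nodes):
        for i in range(nx_nodes):
            lattice[(i, j)] = nid()
            positions[lattice[(i, j)]] = np.array([i * spacing, j * spacing,
                                                   0.0])
    edges: List[Tuple[int, int]] = []

    def connect(a: int, b: int) -> None:
        prev = a
        pa, pb = positions[a], positions[b]
        for k in range(1, samples_per_edge + 1):
            m = nid()
            positions[m] = pa + (pb - pa) * k / (samples_per_edge + 1)
            edges.append((prev, m))
            prev = m
        edges.append((prev, b))

    for j in range(ny_nodes):
        for i in range(nx_nodes):
            if i + 1 < nx_nodes:
                connect(lattice[(i, j)], lattice[(i + 1, j)])
            if j + 1 < ny_nodes:
                connect(lattice[(i, j)], lattice[(i, j + 1)])
    lattice_edges = nx_nodes * (ny_nodes - 1) + ny_nodes * (nx_nodes - 1)
    truth = GroundTruth(1, (nx_nodes - 1) * (ny_nodes - 1),
                        n_segments=lattice_edges - 4)
    return build_network(positions, edges), truth


# ---------------------------------------------------------------------------
# shells, clouds (void fixtures)


def fibonacci_sphere(n: int, radius: float = 1.0,
                     center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Nearly uniform points on a sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = 2 * np.pi * i / GOLDEN
    pts = np.column_stack([np.sin(phi) * np.cos(theta),
                           np.sin(phi) * np.sin(theta),
                           np.cos(phi)]) * radius
    return pts + np.asarray(center, float)


def _knn_edges(pts: np.ndarray, k: int) -> List[Tuple[int, int]]:
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    return sorted({tuple(sorted((i, int(j))))
                   for i, row in enumerate(idx) for j in row[1:]})


def make_hollow_shell(radius: float = 50.0, n_points: int = 400,
                      center=(0.0, 0.0, 0.0), k_neighbors: int = 6
                      ) -> Tuple[VesselNetwork, GroundTruth]:
    """A closed surface-like vessel network enclosing one avascular cavity.

    Fibonacci-sphere samples joined to their 6 nearest neighbors form a
    connected shell whose alpha filtration detects exactly one dominant
    void. Cycle rank is declared from the built graph (Euler formula).
    """
    if radius <= 0 or n_points < 20:
        raise ValueError("shell needs positive radius and >= 20 points")
    pts = fibonacci_sphere(n_points, radius, center)
    net = build_network({i: pts[i] for i in range(n_points)},
                        _knn_edges(pts, k_neighbors))
    truth = GroundTruth(net.n_components, net.cycle_rank, n_voids=1)
    return net, truth


def make_nested_shells(radii: Sequence[float] = (30.0, 60.0),
                       n_points: Sequence[int] = (350, 700),
                       center=(0.0, 0.0, 0.0)
                       ) -> Tuple[VesselNetwork, GroundTruth]:
    """Two concentric shells: two voids (the inner cavity and the gap)."""
    if len(radii) != 2 or len(n_points) != 2 or radii[0] >= radii[1]:
        raise ValueError("need two radii with radii[0] < radii[1]")
    from .network import disjoint_union

    inner, _ = make_hollow_shell(radii[0], n_points[0], center)
    outer, _ = make_hollow_shell(radii[1], n_points[1], center)
    net = disjoint_union(inner, outer)
    truth = GroundTruth(net.n_components, net.cycle_rank, n_voids=2)
    return net, truth


def make_torus_cloud(big_radius: float = 40.0, tube_radius: float = 12.0,
                     n_points: int = 600, seed: int = 0
                     ) -> Tuple[np.ndarray, GroundTruth]:
    """Points on a torus surface: two independent loops and one void.

    At the default density the alpha complex shows Betti numbers
    (1, 2, 1) at mid scale (alpha^2 near 100 um^2 for the default radii);
    hull slivers legitimately carry very large filtration values, so
    top-persistence rankings are less stable than mid-scale Betti counts.
    """
    if tube_radius <= 0 or big_radius <= tube_radius or n_points < 50:
        raise ValueError("invalid torus parameters")
    rng = np.random.default_rng(seed)
    # area-weighted rejection sampling: surface density ~ R + r cos(v)
    u = rng.uniform(0, 2 * np.pi, 4 * n_points)
    v = rng.uniform(0, 2 * np.pi, 4 * n_points)
    accept = rng.uniform(0, 1, 4 * n_points) < (
        (big_radius + tube_radius * np.cos(v))
        / (big_radius + tube_radius))
    u, v = u[accept][:n_points], v[accept][:n_points]
    if len(u) < n_points:
        raise ValueError("rejection sampling starved; lower n_points")
    x = (big_radius + tube_radius * np.cos(v)) * np.cos(u)
    y = (big_radius + tube_radius * np.cos(v)) * np.sin(u)
    z = tube_radius * np.sin(v)
    pts = np.column_stack([x, y, z])
    return pts, GroundTruth(1, 2, n_voids=1)


# ---------------------------------------------------------------------------
# voxelization, perturbation


def voxelize(net: VesselNetwork, spacing=(2.0, 2.0, 2.0)) -> VoxelSkeleton:
    """Rasterize each edge as a 26-connected voxel line.

    Round-trips through :func:`vesseltopo.skeleton.extract_network` preserve
    component count and cycle rank when the network's feature size (minimal
    loop diameter, inter-branch distance) exceeds ~3 voxels.
    """
    if not net.nodes or not net.edges:
        raise ValueError("cannot voxelize an empty network")
    dz, dy, dx = (float(s) for s in spacing)
    if min(dz, dy, dx) <= 0:
        raise ValueError("voxel spacing must be strictly positive")
    coords = net.coords()
    origin = coords.min(axis=0) - np.array([dx, dy, dz])
    scale = np.array([dx, dy, dz])

    def to_idx(p: np.ndarray) -> np.ndarray:
        rel = (p - origin) / scale  # (x, y, z) in voxel units
        return np.rint(rel[..., ::-1]).astype(int)  # -> (z, y, x)

    vox = set()
    for u, v in net.edges:
        a, b = net.nodes[u].xyz, net.nodes[v].xyz
        n_sub = int(np.ceil(np.abs((b - a) / scale).max() * 3)) + 2
        t = np.linspace(0.0, 1.0, n_sub)[:, None]
        for idx in to_idx(a + t * (b - a)):
            vox.add(tuple(idx))
    voxels = np.array(sorted(vox), dtype=int)
    shape = tuple(int(m) + 2 for m in voxels.max(axis=0))
    return VoxelSkeleton(shape=shape, voxels=voxels, spacing=(dz, dy, dx))


def perturb(net: VesselNetwork, sigma: float, seed: int = 0) -> VesselNetwork:
    """Isotropic Gaussian displacement of every node; topology unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    out = net.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for i in out.node_ids():
        out.nodes[i].xyz = out.nodes[i].xyz + rng.standard_normal(3) * sigma
    return out


# ---------------------------------------------------------------------------
# loopy networks with placeable loops, and treatment cohorts


def make_loopy_network(loop_radii: Sequence[float], n_spokes: int = 8,
                       spoke_length: float = 100.0, loop_radius: float = 8.0,
                       loop_points: int = 10, spacing: float = 2.5,
                       seed: int = 0) -> Tuple[VesselNetwork, GroundTruth]:
    """Radial spokes with small vessel loops welded at given radii.

    ``n_spokes`` straight vessels run outward from a central branching
    point; for each entry of ``loop_radii`` a small ring is attached to a
    spoke at that radial distance, oriented outward, adding exactly one
    independent loop born (in the radial filtration around the center) near
    ``radius + 2 * loop_radius``. The loop count is therefore exact ground
    truth and each loop's birth radius is controllable.
    """
    if n_spokes < 3 or spoke_length <= 0 or loop_radius <= 0:
        raise ValueError("invalid loopy-network parameters")
    rng = np.random.default_rng(seed)
    positions: Dict[int, np.ndarray] = {0: np.zeros(3)}
    edges: List[Tuple[int, int]] = []
    counter = [1]

    def nid() -> int:
        counter[0] += 1
        return counter[0] - 1

    n_per_spoke = max(3, int(round(spoke_length / spacing)))
    spoke_nodes: List[List[int]] = []
    directions = []
    for s in range(n_spokes):
        ang = 2 * np.pi * s / n_spokes
        tilt = 0.3 * np.sin(3 * ang + 0.5)  # small out-of-plane variation
        d = np.array([np.cos(ang) * np.cos(tilt),
                      np.sin(ang) * np.cos(tilt), np.sin(tilt)])
        directions.append(d)
        ids = [0]
        for k in range(1, n_per_spoke + 1):
            i = nid()
            positions[i] = d * spoke_length * k / n_per_spoke
            edges.append((ids[-1], i))
            ids.append(i)
        spoke_nodes.append(ids)

    for li, rho in enumerate(loop_radii):
        rho = float(np.clip(rho, 0.15 * spoke_length, 0.95 * spoke_length))
        s = int(rng.integers(n_spokes))
        ids = spoke_nodes[s]
        d = directions[s]
        # attachment node: nearest spoke sample to the requested radius
        k = int(np.clip(round(rho / spoke_length * n_per_spoke), 1,
                        n_per_spoke - 1))
        attach = ids[k]
        perp = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        ring_center = positions[attach] + d * loop_radius
        prev = attach
        for j in range(1, loop_points):
            ang = np.pi + 2 * np.pi * j / loop_points
            i = nid()
            positions[i] = (ring_center
                            + loop_radius * (np.cos(ang) * d
                                             + np.sin(ang) * perp))
            edges.append((prev, i))
            prev = i
        edges.append((prev, attach))

    net = build_network(positions, edges)
    truth = GroundTruth(1, len(loop_radii), n_segments=net.n_segments,
                        extras={"spoke_length": spoke_length})
    return net, truth


def _group_multiplier(group: str, day: float, day_max: float,
                      effect: float) -> float:
    if group == "sprouting_up":
        return 1.0 + effect * day / day_max
    if group == "sprouting_down":
        return 1.0 / (1.0 + effect * day / day_max)
    return 1.0


def make_cohort(n_per_group: int = 5,
                days: Sequence[int] = (0, 1, 2, 3, 4),
                groups: Sequence[str] = ("control", "sprouting_up",
                                         "sprouting_down"),
                base_loops: int = 12, effect: float = 0.5,
                noise: float = 0.1, peripheral: bool = False,
                seed: int = 0) -> pd.DataFrame:
    """Simulated treatment cohort of loopy vessel networks over days.

    Loop density rises toward ``(1 + effect)`` times baseline by the final
    day in the sprouting-up group, falls symmetrically in the
    sprouting-down group, and stays flat in controls; ``noise`` is the
    coefficient of variation of the realized loop count. With
    ``peripheral=True`` the sprouting-up group's *additional* loops are
    placed in the outer radial band (70-90% of the spoke length), emulating
    sprouting concentrated near the tumor periphery; baseline loops keep
    their per-subject positions across days.

    Returns a DataFrame with columns group, day, subject, network (object),
    true_loops.
    """
    if n_per_group < 1 or base_loops < 1 or effect < 0 or noise < 0:
        raise ValueError("invalid cohort parameters")
    rng = np.random.default_rng(seed)
    day_max = float(max(d for d in days if d > 0) if any(d > 0 for d in days)
                    else 1.0)
    spoke_length = 100.0
    rows = []
    for group in groups:
        for subject in range(n_per_group):
            sub_rng = np.random.default_rng(rng.integers(2 ** 31))
            base_radii = sub_rng.uniform(0.2 * spoke_length,
                                         0.85 * spoke_length,
                                         size=3 * base_loops)
            for day in days:
                mult = _group_multiplier(group, float(day), day_max, effect)
                target = base_loops * mult
                n_loops = max(1, int(round(
                    target * (1.0 + noise * sub_rng.standard_normal()))))
                if peripheral and group == "sprouting_up":
                    n_base = min(n_loops, base_loops)
                    radii = list(base_radii[:n_base])
                    extra = n_loops - n_base
                    if extra > 0:
                        radii += list(sub_rng.uniform(0.7 * spoke_length,
                                                      0.9 * spoke_length,
                                                      size=extra))
                else:
                    radii = list(base_radii[:n_loops])
                net, truth = make_loopy_network(
                    radii, spoke_length=spoke_length,
                    seed=int(sub_rng.integers(2 ** 31)))
                rows.append({"group": group, "day": day, "subject":
                             f"{group}_{subject}", "network": net,
                             "true_loops": len(radii)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dispatcher


_NETWORK_KINDS = {
    "straight": make_straight,
    "sinusoid": make_sinusoid,
    "helix": make_helix,
    "tree": make_tree,
    "grid": make_grid,
    "ring": make_ring,
    "hollow_shell": make_hollow_shell,
    "nested_shells": make_nested_shells,
    "random_walk": make_random_walk,
    "loopy": make_loopy_network,
}
_CLOUD_KINDS = {"torus_cloud": make_torus_cloud}


def generate(spec: GeneratorSpec
             ) -> Tuple[Union[VesselNetwork, np.ndarray], GroundTruth]:
    """Instantiate a :class:`GeneratorSpec`; seed fully determines output."""
    params = dict(spec.params)
    if spec.kind in _NETWORK_KINDS:
        fn = _NETWORK_KINDS[spec.kind]
        if spec.kind in ("random_walk", "loopy"):
            params.setdefault("seed", spec.seed)
        return fn(**params)
    if spec.kind in _CLOUD_KINDS:
        params.setdefault("seed", spec.seed)
        return _CLOUD_KINDS[spec.kind](**params)
    raise ValueError(f"unknown generator kind {spec.kind!r}")
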