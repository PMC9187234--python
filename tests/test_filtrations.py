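"""Radial and alpha-complex filtration construction."""

import numpy as np
import pytest
from scipy.spatial import Delaunay
from scipy.spatial.transform import Rotation

from vesseltopo import synthetic as syn
from vesseltopo.filtrations import (alpha_filtration, center_of_mass,
                                    jitter_points, radial_filtration,
                                    restrict_to_ball)
from vesseltopo.network import build_network


class TestCenterOfMass:
    def test_midpoint_of_two_nodes(self):
        net = build_network({0: (0, 0, 0), 1: (2, 0, 0)}, [(0, 1)])
        assert center_of_mass(net) == pytest.approx([1, 0, 0])

    def test_symmetric_set_centers_on_symmetry_point(self):
        p = np.array([3.0, -2.0, 7.0])
        pos = {i: p + d for i, d in enumerate(
            [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
             (0, 0, 1), (0, 0, -1)])}
        net = build_network(pos, [(0, 2), (2, 1), (1, 3), (3, 0), (4, 5)])
        assert center_of_mass(net) == pytest.approx(p)

    def test_translation_equivariance(self, grid_network):
        net, _ = grid_network
        t = np.array([10.0, -5.0, 2.0])
        assert center_of_mass(net.translate(t)) == pytest.approx(
            center_of_mass(net) + t)


class TestRadialFiltration:
    def test_farthest_node_enters_at_r_max(self, path_network):
        filt = radial_filtration(path_network, center=(0, 0, 0), n_steps=500)
        assert filt.node_steps[9] == 500
        assert filt.node_value(9) == pytest.approx(filt.r_max)

    def test_edge_value_is_max_of_endpoints(self, path_network):
        filt = radial_filtration(path_network, center=(0, 0, 0), n_steps=9)
        for u, v in path_network.edges:
            assert filt.edge_step(u, v) == max(filt.node_steps[u],
                                               filt.node_steps[v])

    def test_node_on_grid_radius_enters_at_that_radius(self):
        # nodes at 1..4 um from center, r_max 4, 4 steps of 1 um
        pos = {i: (float(i + 1), 0, 0) for i in range(4)}
        net = build_network(pos, [(i, i + 1) for i in range(3)])
        filt = radial_filtration(net, center=(0, 0, 0), n_steps=4)
        assert [filt.node_steps[i] for i in range(4)] == [1, 2, 3, 4]

    def test_rotation_invariance_about_center(self, grid_network):
        net, _ = grid_network
        c = center_of_mass(net)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        rotated = net.translate(-c).transform(rot).translate(c)
        a = radial_filtration(net, center=c, n_steps=500)
        b = radial_filtration(rotated, center=c, n_steps=500)
        assert a.node_steps == b.node_steps

    def test_restriction_nesting_and_extremes(self, grid_network):
        net, _ = grid_network
        filt = radial_filtration(net, n_steps=100)
        empty = restrict_to_ball(filt, 0.0)
        assert empty.number_of_nodes() == 0
        full = restrict_to_ball(filt, filt.r_max)
        assert full.number_of_nodes() == net.n_nodes
        assert full.number_of_edges() == net.n_edges
        prev = set()
        for r in np.linspace(0, filt.r_max, 7):
            cur = set(restrict_to_ball(filt, r).nodes)
            assert prev <= cur
            prev = cur


class TestAlphaFiltration:
    def test_regular_tetrahedron_closed_form(self):
        a = 10.0
        pts = np.array([[0, 0, 0], [a, 0, 0],
                        [a / 2, a * np.sqrt(3) / 2, 0],
                        [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2 / 3)]])
        filt = alpha_filtration(pts)
        tris = [v for _, d, v in filt.simplices if d == 2]
        tets = [v for _, d, v in filt.simplices if d == 3]
        assert tris == pytest.approx([a ** 2 / 3] * 4, rel=1e-9)
        assert tets == pytest.approx([3 * a ** 2 / 8], rel=1e-9)

    def test_slim_triangle_long_edge_delayed(self):
        # slim obtuse triangle: its long edge is not Gabriel and must enter
        # together with the triangle, not at its own circumradius
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0], [5.0, 0.5, 0],
                        [5.0, 3.0, 40.0]])
        filt = alpha_filtration(pts)
        values = {verts: v for verts, _, v in filt.simplices}
        long_edge = values[(0, 1)]
        slim_tri = values[(0, 1, 2)]
        assert long_edge == pytest.approx(slim_tri)
        assert long_edge > 25.0  # own circumradius^2 would be 25

    def test_face_monotonicity(self):
        rng = np.random.default_rng(2)
        filt = alpha_filtration(rng.uniform(0, 50, (30, 3)))
        values = {verts: v for verts, _, v in filt.simplices}
        for verts, dim, v in filt.simplices:
            for k in range(dim + 1):
                face = verts[:k] + verts[k + 1:]
                if face:
                    assert values[face] <= v + 1e-9 * (1 + v)

    def test_final_complex_is_delaunay(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 40, (40, 3))
        filt = alpha_filtration(pts)
        n_tets = sum(1 for _, d, _ in filt.simplices if d == 3)
        assert n_tets == len(Delaunay(pts).simplices)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 30, (25, 3))
        rot = Rotation.from_euler("zyx", [0.7, -0.2, 1.9]).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -3.0, 11.0])
        va = sorted(v for _, _, v in alpha_filtration(pts).simplices)
        vb = sorted(v for _, _, v in alpha_filtration(moved).simplices)
        assert np.allclose(va, vb, rtol=1e-9, atol=1e-9)

    def test_too_few_or_coplanar_points_rejected(self):
        with pytest.raises(ValueError):
            alpha_filtration(np.zeros((3, 3)))
        flat = np.column_stack([np.arange(10.0), np.arange(10.0) ** 2,
                                np.zeros(10)])
        with pytest.raises(ValueError, match="jitter"):
            alpha_filtration(flat)

    def test_jitter_makes_lattice_triangulable(self):
        lattice = np.array([(x, y, z) for x in range(3) for y in range(3)
                            for z in range(3)], dtype=float)
        filt = alpha_filtration(jitter_points(lattice, seed=0))
        assert filt.end_value > 0
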