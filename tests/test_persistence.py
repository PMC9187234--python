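"""Persistence computation: union-find sweep, matrix reduction, oracles."""

import numpy as np
import pytest

from vesseltopo.filtrations import (SimplicialFiltration, alpha_filtration,
                                    radial_filtration)
from vesseltopo.network import build_network
from vesseltopo.persistence import (Barcode, betti_curve,
                                    betti_curve_bruteforce, oracle_betti,
                                    persist_dim0_graph, persist_dim1_graph,
                                    persist_graph, persist_simplicial)


def random_spatial_graph(rng, n_nodes=15, p_edge=0.2):
    pos = {i: rng.uniform(0, 100, 3) for i in range(n_nodes)}
    edges = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)
             if rng.uniform() < p_edge]
    return build_network(pos, edges)


class TestGraphDim0:
    def test_path_all_same_value_one_essential(self):
        # nodes equidistant from center: n bars, n-1 of zero persistence
        n = 6
        pos = {i: (np.cos(i), np.sin(i), 0.0) for i in range(n)}
        net = build_network(pos, [(i, i + 1) for i in range(n - 1)])
        bc = persist_dim0_graph(radial_filtration(net, center=(0, 0, 0),
                                                  n_steps=10))
        assert bc.n_bars() == n
        assert bc.n_essential() == 1
        assert sum(1 for b in bc.bars
                   if b.persistence == 0 and not b.essential) == n - 1

    def test_elder_rule_two_nodes(self):
        net = build_network({0: (1.0, 0, 0), 1: (2.0, 0, 0)}, [(0, 1)])
        bc = persist_dim0_graph(radial_filtration(net, center=(0, 0, 0),
                                                  n_steps=2))
        bars = sorted(bc.bars, key=lambda b: b.birth)
        assert bars[0].essential and bars[0].birth == pytest.approx(1.0)
        assert not bars[1].essential
        assert bars[1].birth == bars[1].death == pytest.approx(2.0)

    def test_bar_count_equals_node_count(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = random_spatial_graph(rng)
            bc = persist_dim0_graph(radial_filtration(net, n_steps=20))
            assert bc.n_bars() == net.n_nodes
            assert bc.n_essential() == net.n_components


class TestGraphDim1:
    def test_tree_has_no_loops(self, tree_network):
        net, _ = tree_network
        bc = persist_dim1_graph(radial_filtration(net, n_steps=100))
        assert bc.n_bars() == 0

    def test_single_cycle_one_essential_bar(self):
        from vesseltopo.synthetic import make_ring

        net, _ = make_ring(radius=20, n_points=12)
        bc = persist_dim1_graph(radial_filtration(net, n_steps=50))
        assert bc.n_bars() == 1
        assert bc.bars[0].essential
        assert bc.bars[0].death == pytest.approx(bc.end_value)

    def test_grid_rank_four(self, grid_network):
        net, truth = grid_network
        bc = persist_dim1_graph(radial_filtration(net, n_steps=500))
        assert bc.n_bars() == truth.cycle_rank == 4

    def test_count_is_euler_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            net = random_spatial_graph(rng)
            bc = persist_dim1_graph(radial_filtration(net, n_steps=25))
            assert bc.n_bars() == (net.n_edges - net.n_nodes
                                   + net.n_components)


class TestSimplicial:
    def test_filtered_triangle_textbook(self):
        simplices = [((0,), 0, 0.0), ((1,), 0, 0.0), ((2,), 0, 0.0),
                     ((0, 1), 1, 1.0), ((0, 2), 1, 1.0), ((1, 2), 1, 1.0),
                     ((0, 1, 2), 2, 2.0)]
        filt = SimplicialFiltration(points=np.zeros((3, 3)),
                                    simplices=simplices)
        bc = persist_simplicial(filt)
        d0 = sorted((b.birth, b.death, b.essential) for b in bc.in_dim(0))
        assert d0 == [(0.0, 1.0, False), (0.0, 1.0, False),
                      (0.0, 2.0, True)]
        d1 = [(b.birth, b.death) for b in bc.in_dim(1)]
        assert d1 == [(1.0, 2.0)]

    def test_hollow_tetrahedron_has_one_void(self):
        verts = [((i,), 0, 0.0) for i in range(4)]
        edges = [((i, j), 1, 1.0) for i in range(4) for j in range(i + 1, 4)]
        tris = [((0, 1, 2), 2, 2.0), ((0, 1, 3), 2, 2.0),
                ((0, 2, 3), 2, 2.0), ((1, 2, 3), 2, 2.0)]
        filt = SimplicialFiltration(points=np.zeros((4, 3)),
                                    simplices=verts + edges + tris)
        bc = persist_simplicial(filt)
        essential2 = [b for b in bc.in_dim(2) if b.essential]
        assert len(essential2) == 1
        assert len(bc.in_dim(2)) == 1

    def test_non_monotone_input_rejected(self):
        bad = [((0,), 0, 0.0), ((1,), 0, 0.0), ((0, 1), 1, -1.0)]
        filt = SimplicialFiltration(points=np.zeros((2, 3)), simplices=bad)
        with pytest.raises(ValueError):
            persist_simplicial(filt)

    def test_determinism(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 50, (20, 3))
        a = persist_simplicial(alpha_filtration(pts))
        b = persist_simplicial(alpha_filtration(pts.copy()))
        assert a.bars == b.bars


class TestBettiCurve:
    def test_empty_barcode(self):
        curve = betti_curve(Barcode([], 1.0), np.linspace(0, 1, 5))
        assert curve.beta(0).sum() == 0

    def test_half_open_convention(self):
        from vesseltopo.persistence import Bar

        bc = Barcode([Bar(0, 1.0, 3.0)], 4.0)
        curve = betti_curve(bc, [0, 1, 2, 3, 4])
        assert curve.beta(0).tolist() == [0, 1, 1, 0, 0]

    def test_grid_refinement_consistent(self):
        from vesseltopo.persistence import Bar

        bc = Barcode([Bar(0, 0.5, 2.5), Bar(1, 1.0, 4.0, True)], 4.0)
        coarse = betti_curve(bc, [0, 1, 2, 3, 4])
        fine = betti_curve(bc, np.linspace(0, 4, 17))
        for i, v in enumerate([0, 1, 2, 3, 4]):
            j = np.searchsorted(fine.grid, v)
            assert coarse.beta(0)[i] == fine.beta(0)[j]
            assert coarse.beta(1)[i] == fine.beta(1)[j]


class TestOracle:
    def test_single_vertex(self):
        filt = SimplicialFiltration(points=np.zeros((1, 3)),
                                    simplices=[((0,), 0, 0.0)])
        assert oracle_betti(filt, 0.0, 0) == 1

    def test_circle_complex(self):
        n = 6
        verts = [((i,), 0, 0.0) for i in range(n)]
        edges = [(tuple(sorted((i, (i + 1) % n))), 1, 1.0) for i in range(n)]
        filt = SimplicialFiltration(points=np.zeros((n, 3)),
                                    simplices=verts + edges)
        assert oracle_betti(filt, 1.0, 0) == 1
        assert oracle_betti(filt, 1.0, 1) == 1

    def test_alpha_barcode_matches_dense_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 60, (18, 3))
        filt = alpha_filtration(pts)
        bc = persist_simplicial(filt)
        grid = np.unique([v for _, _, v in filt.simplices])[::5]
        curve = betti_curve(bc, grid)
        for dim in (0, 1, 2):
            oracle = [oracle_betti(filt, v, dim) for v in grid]
            assert curve.beta(dim).tolist() == oracle

    def test_bruteforce_curve_matches_dense_oracle(self):
        rng = np.random.default_rng(12)
        filt = alpha_filtration(rng.uniform(0, 60, (15, 3)))
        grid = np.unique([v for _, _, v in filt.simplices])[::4]
        brute = betti_curve_bruteforce(filt, grid)
        for dim in (0, 1, 2):
            oracle = [oracle_betti(filt, v, dim) for v in grid]
            assert brute.beta(dim).tolist() == oracle


def test_graph_persistence_deterministic(grid_network):
    net, _ = grid_network
    filt = radial_filtration(net, n_steps=500)
    a0, a1 = persist_graph(filt)
    b0, b1 = persist_graph(filt)
    assert a0.bars == b0.bars and a1.bars == b1.bars
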