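"""Descriptor behavior: topological tortuosity, loops, voids, clr, SOAM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesseltopo import synthetic as syn
from vesseltopo.descriptors import (clr, compute_all, loops_per_segment,
                                    soam, topological_tortuosity,
                                    void_descriptor)
from vesseltopo.filtrations import radial_filtration
from vesseltopo.network import build_network, disjoint_union
from vesseltopo.persistence import Bar, Barcode, persist_graph, \
    persist_simplicial
from vesseltopo.filtrations import alpha_filtration


class TestTopologicalTortuosity:
    def test_short_bar_rule_on_explicit_barcode(self):
        R = 100.0
        bc = Barcode([Bar(0, 0.0, 0.05 * R), Bar(0, 0.0, 0.2 * R),
                      Bar(0, 0.0, R, True)], R)
        assert topological_tortuosity(bc, 2) == pytest.approx(0.5)

    def test_straight_radial_vessel_scores_zero(self):
        net, _ = syn.make_straight(length=100, spacing=2.0)
        filt = radial_filtration(net, center=(0, 0, 0), n_steps=500)
        bc0, _ = persist_graph(filt)
        assert bc0.n_essential() == 1
        assert topological_tortuosity(bc0, 1) == 0.0

    def test_helix_beats_straight_at_same_center(self):
        center = (2000.0, 0.0, 0.0)
        helix, _ = syn.make_helix(turns=6, radius=5, arc_length=300)
        straight, _ = syn.make_straight(length=300, spacing=1.5,
                                        direction=(0, 0, 1),
                                        origin=(0, 0, -150))
        scores = {}
        for name, net in [("helix", helix), ("straight", straight)]:
            bc0, _ = persist_graph(radial_filtration(net, center=center,
                                                     n_steps=500))
            scores[name] = topological_tortuosity(bc0, net.n_segments)
        assert scores["helix"] > scores["straight"]

    def test_zero_segments_rejected(self):
        with pytest.raises(ValueError):
            topological_tortuosity(Barcode([], 1.0), 0)

    def test_include_zero_bars_switch(self):
        bc = Barcode([Bar(0, 1.0, 1.0), Bar(0, 0.0, 10.0, True)], 10.0)
        assert topological_tortuosity(bc, 1) == 0.0
        assert topological_tortuosity(bc, 1, include_zero_bars=True) == 1.0


class TestLoopsPerSegment:
    def test_tree_is_zero(self, tree_network):
        net, _ = tree_network
        _, bc1 = persist_graph(radial_filtration(net, n_steps=100))
        assert loops_per_segment(bc1, net.n_segments) == 0.0

    def test_self_loop_network_is_one(self):
        net, _ = syn.make_ring(radius=25, n_points=16)
        _, bc1 = persist_graph(radial_filtration(net, n_steps=100))
        assert loops_per_segment(bc1, net.n_segments) == 1.0

    def test_grid_matches_euler_formula(self, grid_network):
        net, truth = grid_network
        _, bc1 = persist_graph(radial_filtration(net, n_steps=500))
        lps = loops_per_segment(bc1, net.n_segments)
        assert lps * net.n_segments == pytest.approx(
            net.n_edges - net.n_nodes + net.n_components)
        assert lps == pytest.approx(truth.cycle_rank / truth.n_segments)


class TestVoidDescriptor:
    def test_empty_barcode_is_zero(self):
        assert void_descriptor(Barcode([], 10.0)) == 0.0

    def test_hollow_shell_median_is_dominant_bar(self):
        net, _ = syn.make_hollow_shell(radius=50, n_points=400)
        bc = persist_simplicial(alpha_filtration(net.coords()))
        pers = sorted(bc.persistences(dim=2))[::-1]
        assert void_descriptor(bc) == pytest.approx(pers[0])
        # the cavity dies when alpha reaches the shell radius
        assert pers[0] == pytest.approx(50.0 ** 2, rel=0.05)

    def test_larger_shell_larger_median(self):
        meds = []
        for radius in (30.0, 60.0):
            net, _ = syn.make_hollow_shell(radius=radius, n_points=400)
            bc = persist_simplicial(alpha_filtration(net.coords()))
            meds.append(void_descriptor(bc))
        assert meds[1] > meds[0]


class TestClr:
    def test_collinear_is_one(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [3, 3, 3]], float)
        assert clr(pts) == pytest.approx(1.0)

    def test_right_angle_closed_form(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        assert clr(pts) == pytest.approx(np.sqrt(2) / 2)

    def test_closed_loop_is_zero(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0]], float)
        assert clr(pts) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            clr(np.zeros((3, 3)))


class TestSoam:
    def test_straight_vessel_is_zero(self):
        pts = np.column_stack([np.linspace(0, 50, 26), np.zeros(26),
                               np.zeros(26)])
        assert soam(pts).total_degrees == pytest.approx(0.0, abs=1e-9)

    def test_single_right_angle_elbow(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0],
                        [2, 1, 0], [2, 2, 0]], float)
        assert soam(pts, step=1.0).total_degrees == pytest.approx(90.0)

    def test_degenerate_two_points_scores_zero(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], float)
        assert soam(pts, step=5.0).total_degrees == 0.0


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_clr_and_soam_bounds_on_random_walks(seed):
    net, _ = syn.make_random_walk(n_steps=40, seed=seed)
    pts = net.segment_coords(net.segments[0])
    assert 0.0 < clr(pts) <= 1.0 + 1e-12
    assert soam(pts).total_degrees >= 0.0


class TestMonotonicityBattery:
    def test_helix_family_fixed_length(self):
        """More turns at fixed arc length: tortuosity and SOAM rise, clr
        falls."""
        center = (2000.0, 0.0, 0.0)
        torts, soams, clrs = [], [], []
        for turns in (2, 4, 6, 8):
            net, _ = syn.make_helix(turns=turns, radius=5, arc_length=300)
            bc0, _ = persist_graph(radial_filtration(net, center=center,
                                                     n_steps=500))
            torts.append(topological_tortuosity(bc0, net.n_segments))
            pts = net.segment_coords(net.segments[0])
            soams.append(soam(pts).total_degrees)
            clrs.append(clr(pts))
        assert all(a < b for a, b in zip(torts, torts[1:]))
        assert all(a < b for a, b in zip(soams, soams[1:]))
        assert all(a > b for a, b in zip(clrs, clrs[1:]))

    def test_disjoint_union_doubling_leaves_ratios_unchanged(self):
        center = np.zeros(3)
        helix, _ = syn.make_helix(turns=5, radius=5, arc_length=300,
                                  center=(800.0, 0, 0))
        ring, _ = syn.make_ring(radius=30, center=(200.0, 0, 0))
        for net in (helix, ring):
            double = disjoint_union(net, net.transform(-np.eye(3)))
            vals = []
            for n in (net, double):
                bc0, bc1 = persist_graph(radial_filtration(n, center=center,
                                                           n_steps=500))
                vals.append((topological_tortuosity(bc0, n.n_segments),
                             loops_per_segment(bc1, n.n_segments)))
            assert vals[0] == pytest.approx(vals[1])


class TestComputeAll:
    def test_matches_individual_ops_and_absent_fields(self, tree_network):
        net, _ = tree_network
        filt = radial_filtration(net, n_steps=200)
        bc0, bc1 = persist_graph(filt)
        ds = compute_all(net, bc0=bc0, bc1=bc1)
        assert ds.loops_per_segment == loops_per_segment(bc1, net.n_segments)
        assert ds.tortuosity_topological == topological_tortuosity(
            bc0, net.n_segments)
        assert ds.void_median_persistence is None  # no alpha barcode given
        assert ds.n_loops == 0

    def test_csv_round_trip(self, tmp_path, grid_network):
        from vesseltopo.descriptors import DescriptorSet

        net, _ = grid_network
        bc0, bc1 = persist_graph(radial_filtration(net, n_steps=100))
        ds = compute_all(net, bc0=bc0, bc1=bc1)
        p = tmp_path / "ds.csv"
        ds.to_frame().to_csv(p, index=False)
        import pandas as pd

        back = DescriptorSet.from_frame(pd.read_csv(p))
        assert back.loops_per_segment == pytest.approx(ds.loops_per_segment)
        assert back.n_segments == ds.n_segments
        assert back.void_median_persistence is None


def test_rigid_motion_invariance_of_radial_descriptors(grid_network):
    from scipy.spatial.transform import Rotation

    net, _ = grid_network
    rot = Rotation.from_euler("xyz", [1.0, 0.4, -0.7]).as_matrix()
    moved = net.transform(rot).translate([40.0, -10.0, 25.0])
    vals = []
    for n in (net, moved):
        bc0, bc1 = persist_graph(radial_filtration(n, n_steps=500))
        vals.append((topological_tortuosity(bc0, n.n_segments),
                     loops_per_segment(bc1, n.n_segments)))
    assert vals[0] == pytest.approx(vals[1])
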