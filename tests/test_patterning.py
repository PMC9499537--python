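"""Spatial patterning: DBSCAN oracle, heat maps, nodes, quantification."""

import numpy as np
import pandas as pd
import pytest
import shapely.geometry as geom
from scipy.stats import binom

from erkwave import (
    NodeSet,
    SimConfig,
    accumulate_heatmap,
    assign_compartments,
    cluster_erk_active,
    detect_nodes,
    localize_events,
    nearest_nuclei_distances,
    quantify_channel_per_cell,
    simulate,
)


def active_frame(points, active=None):
    df = pd.DataFrame(points, columns=["x_um", "y_um"])
    df["erk_active"] = True if active is None else active
    return df


def brute_force_dbscan(points, eps, min_pts):
    """Textbook density-reachability DBSCAN.

    Returns (labels, core_mask); border points may legitimately belong to
    any cluster owning a core point within eps, so comparisons must allow
    that ambiguity.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels, core


class TestDbscanClustering:
    def test_two_distant_groups_two_clusters(self):
        rng = np.random.default_rng(70)
        g1 = rng.normal([100, 100], 10, size=(10, 2))
        g2 = rng.normal([600, 100], 10, size=(10, 2))
        df, polys = cluster_erk_active(active_frame(np.vstack([g1, g2])),
                                       eps_um=50.0, min_pts=5)
        assert df["cluster"].nunique() == 2
        assert len(polys) == 2

    def test_sparse_points_all_noise(self):
        pts = np.array([[0.0, 0.0], [200.0, 0.0], [0.0, 200.0]])
        df, polys = cluster_erk_active(active_frame(pts), eps_um=50.0,
                                       min_pts=2)
        assert (df["cluster"] == -1).all()
        assert polys == []

    def test_no_active_cells_empty(self):
        df, polys = cluster_erk_active(
            active_frame(np.zeros((4, 2)), active=False))
        assert len(df) == 0 and polys == []

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_density_reachability_oracle(self, seed):
        """Cluster structure matches the textbook DBSCAN definition on
        random <= 50-point instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        pts = rng.uniform(0, 200, size=(n, 2))
        eps, min_pts = 30.0, 4
        df, _ = cluster_erk_active(active_frame(pts), eps_um=eps,
                                   min_pts=min_pts)
        got = df["cluster"].to_numpy()
        want, core = brute_force_dbscan(pts, eps, min_pts)
        # core points: identical partition up to relabelling
        for a in range(n):
            for b in range(n):
                if core[a] and core[b]:
                    assert (got[a] == got[b]) == (want[a] == want[b])
        # noise agrees exactly; border points sit in a cluster that owns a
        # core point within eps
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        for i in range(n):
            if want[i] == -1 and not core[i]:
                near_core = core & (d[i] <= eps)
                if not near_core.any():
                    assert got[i] == -1
            if core[i]:
                assert got[i] != -1


class TestHeatmap:
    def test_static_cluster_counts_frames(self):
        square = geom.Polygon([(2, 2), (10, 2), (10, 10), (2, 10)])
        heat = accumulate_heatmap([[square]] * 10, (14, 14), pixel_size=1.0)
        assert heat[5, 5] == 10
        assert heat[12, 12] == 0
        assert heat.max() <= 10

    def test_no_regions_all_zero(self):
        heat = accumulate_heatmap([[], [], []], (8, 8), pixel_size=1.0)
        assert heat.sum() == 0

    def test_moving_cluster_matches_point_in_polygon_oracle(self):
        rng = np.random.default_rng(71)
        frames = []
        for f in range(6):
            pts = rng.uniform(5 + 3 * f, 25 + 3 * f, size=(8, 2))
            frames.append([geom.MultiPoint(pts).convex_hull])
        heat = accumulate_heatmap(frames, (50, 50), pixel_size=1.0)
        # oracle: shapely contains() per pixel centre per frame
        for r in range(0, 50, 7):
            for c in range(0, 50, 7):
                p = geom.Point(c, r)
                expect = sum(poly.contains(p)
                             for polys in frames for poly in polys)
                assert heat[r, c] == expect


class TestDetectNodes:
    def test_lattice_of_dense_clusters_exact_spacing(self):
        rng = np.random.default_rng(72)
        a = 300.0
        pts = []
        for i in range(4):
            for j in range(4):
                c = np.array([150 + i * a, 150 + j * a])
                pts.append(c + rng.normal(0, 12, size=(40, 2)))
        pts.append(rng.uniform(0, 1200, size=(80, 2)))  # sparse background
        ns = detect_nodes(np.vstack(pts), (1200.0, 1200.0))
        assert ns.n_nodes == 16
        assert np.allclose(ns.spacing, a, atol=0.05 * a)

    def test_uniform_field_no_nodes(self):
        rng = np.random.default_rng(73)
        pts = rng.uniform(0, 1500, size=(1000, 2))
        ns = detect_nodes(pts, (1500.0, 1500.0))
        assert ns.n_nodes == 0

    def test_needs_at_least_one_nucleus(self):
        with pytest.raises(ValueError):
            detect_nodes(np.empty((0, 2)), (100.0, 100.0))

    def test_patterned_truth_spacing_recovered(self, patterned_truth):
        """Mean recovered node spacing within 10% of the 399 µm set-point."""
        gt, cfg = patterned_truth
        pts = gt.cells[gt.cells["frame"] == 0][["x_um", "y_um"]].to_numpy()
        ns = detect_nodes(pts, cfg.field_size)
        assert ns.n_nodes >= 9
        assert np.mean(ns.spacing) == pytest.approx(399.0, rel=0.10)


class TestCompartments:
    def test_cell_at_node_centroid_is_node(self, patterned_truth):
        gt, cfg = patterned_truth
        pts = gt.cells[gt.cells["frame"] == 0][["x_um", "y_um"]].to_numpy()
        ns = detect_nodes(pts, cfg.field_size)
        probes = ns.table.rename(columns={"x_um": "x_um", "y_um": "y_um"})
        comp = assign_compartments(probes, ns)
        assert (comp == "node").all()

    def test_distant_cell_is_nonnode(self):
        ns = NodeSet(
            table=pd.DataFrame({"node_id": [0], "x_um": [10.0],
                                "y_um": [10.0], "area_um2": [100.0]}),
            polygons=[geom.Point(10, 10).buffer(10.0)],
            spacing=np.empty(0),
        )
        comp = assign_compartments(
            pd.DataFrame({"x_um": [5000.0], "y_um": [5000.0]}), ns)
        assert comp.iloc[0] == "non-node"

    def test_agreement_with_ground_truth(self, patterned_truth):
        gt, cfg = patterned_truth
        f0 = gt.cells[gt.cells["frame"] == 0]
        ns = detect_nodes(f0[["x_um", "y_um"]].to_numpy(), cfg.field_size)
        comp = assign_compartments(f0, ns)
        agree = (comp.to_numpy() == f0["compartment"].to_numpy()).mean()
        assert agree >= 0.95

    def test_every_cell_labelled(self, patterned_truth):
        gt, cfg = patterned_truth
        f0 = gt.cells[gt.cells["frame"] == 0]
        ns = detect_nodes(f0[["x_um", "y_um"]].to_numpy(), cfg.field_size)
        comp = assign_compartments(f0, ns)
        assert set(comp.unique()) <= {"node", "non-node"}
        assert len(comp) == len(f0)


class TestQuantify:
    def make_label_map(self):
        from erkwave.segmentation import LabelMap, _props

        labels = np.zeros((40, 60), dtype=np.int32)
        labels[10:20, 10:20] = 1  # 100-px square nucleus
        labels[25:30, 40:50] = 2  # 50-px nucleus
        return LabelMap(labels=labels, table=_props(labels))

    def test_uniform_intensity_sum_and_mean(self):
        lm = self.make_label_map()
        channel = np.full((40, 60), 3.0)
        s = quantify_channel_per_cell(channel, lm, mode="sum")
        m = quantify_channel_per_cell(channel, lm, mode="mean")
        assert s[s.label == 1]["intensity"].iloc[0] == pytest.approx(300.0)
        assert s[s.label == 2]["intensity"].iloc[0] == pytest.approx(150.0)
        assert np.allclose(m["intensity"], 3.0)

    def test_five_fold_brighter_population_recovered(self, patterned_truth):
        """Node cells given 5x signal show a 5x MFI ratio after the full
        label-and-measure round trip."""
        from erkwave import render
        from erkwave.segmentation import segment_nuclei

        cfg = SimConfig(field_size=(600.0, 600.0), n_frames=1,
                        node_spacing_mean=300.0, node_radius=70.0,
                        noise_sd=0.0, jitter_sd=0.0, rng_seed=74)
        rng = np.random.default_rng(74)
        gt = simulate(cfg, rng)
        stack = render(gt, cfg, rng)
        lm = segment_nuclei(stack.channel("H2B")[0])
        # synthesise a FISH-like channel: node-cell pixels 5x brighter
        f0 = gt.cells[gt.cells["frame"] == 0]
        channel = np.ones(stack.shape_px)
        centers = gt.nodes[["x_um", "y_um"]].to_numpy() / cfg.pixel_size
        rr, cc = np.mgrid[0:stack.shape_px[0], 0:stack.shape_px[1]]
        for cx, cy in centers:
            inside = np.hypot(cc - cx, rr - cy) <= cfg.node_radius / cfg.pixel_size
            channel[inside] = 5.0
        q = quantify_channel_per_cell(channel, lm, mode="mean")
        comp = assign_compartments(
            q.assign(x_um=q["x_px"] * cfg.pixel_size,
                     y_um=q["y_px"] * cfg.pixel_size),
            NodeSet(table=gt.nodes.assign(area_um2=0.0),
                    polygons=[geom.Point(x, y).buffer(cfg.node_radius)
                              for x, y in gt.nodes[["x_um", "y_um"]].to_numpy()],
                    spacing=np.empty(0)),
        )
        ratio = (q[comp == "node"]["intensity"].mean()
                 / q[comp == "non-node"]["intensity"].mean())
        assert ratio == pytest.approx(5.0, rel=0.10)

    def test_zero_channel_low_gate(self):
        lm = self.make_label_map()
        q = quantify_channel_per_cell(np.zeros((40, 60)), lm, mode="sum",
                                      gate_threshold=1.0)
        assert (q["intensity"] == 0.0).all()
        assert (q["gate"] == "low").all()

    def test_shape_mismatch_rejected(self):
        lm = self.make_label_map()
        with pytest.raises(ValueError):
            quantify_channel_per_cell(np.zeros((10, 10)), lm)


class TestNearestNeighbours:
    def test_square_lattice_constant(self):
        a = 7.0
        xx, yy = np.meshgrid(np.arange(5) * a, np.arange(5) * a)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        assert np.allclose(nearest_nuclei_distances(pts), a)

    def test_two_points(self):
        d = nearest_nuclei_distances(np.array([[0.0, 0.0], [7.0, 0.0]]))
        assert np.allclose(d, 7.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(75)
        pts = rng.uniform(0, 100, size=(100, 2))
        fast = nearest_nuclei_distances(pts)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(fast, d.min(axis=1))

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            nearest_nuclei_distances(np.array([[1.0, 2.0]]))


class TestLocalizeEvents:
    def truth_nodeset(self, gt):
        polys = [geom.Point(x, y).buffer(r) for x, y, r in
                 gt.nodes[["x_um", "y_um", "radius_um"]].to_numpy()]
        return NodeSet(table=gt.nodes.assign(area_um2=0.0), polygons=polys,
                       spacing=np.empty(0))

    def test_all_nonnode_when_p_is_one(self):
        cfg = SimConfig(field_size=(1200.0, 1200.0), apoptosis_rate=0.8,
                        p_nonnode=1.0, n_frames=25, migration_gain=0.0,
                        wave_extent=60.0, duration_at_origin=10.0,
                        recoil_distance=0.0, rng_seed=76)
        gt = simulate(cfg)
        counts = localize_events(gt.events, self.truth_nodeset(gt))
        assert counts["n_node"] == 0
        assert counts["frac_nonnode"] == 1.0

    def test_no_events_zero_counts(self):
        cfg = SimConfig(field_size=(900.0, 900.0), apoptosis_rate=0.0,
                        n_frames=3, rng_seed=77)
        gt = simulate(cfg)
        counts = localize_events(gt.events, self.truth_nodeset(gt))
        assert counts["n_node"] == 0 and counts["n_nonnode"] == 0

    def test_nonnode_fraction_in_binomial_ci(self):
        cfg = SimConfig(field_size=(1600.0, 1600.0), apoptosis_rate=4.0,
                        p_nonnode=0.8, n_frames=50, migration_gain=0.0,
                        wave_extent=60.0, duration_at_origin=10.0,
                        recoil_distance=0.0, jitter_sd=0.0, rng_seed=78)
        gt = simulate(cfg)
        counts = localize_events(gt.events, self.truth_nodeset(gt))
        n = counts["n_node"] + counts["n_nonnode"]
        assert n >= 150
        lo, hi = binom.ppf([0.025, 0.975], n, 0.8)
        assert lo <= counts["n_nonnode"] <= hi


class TestRegimePresets:
    def test_global_activation_disperses_nodes(self):
        from erkwave import fixture_config

        cfg = fixture_config("fig4_pma", seed=80)
        gt = simulate(cfg)
        assert (gt.cells["E"] == 1.0).all()
        pts = gt.cells[gt.cells["frame"] == 0][["x_um", "y_um"]].to_numpy()
        ns = detect_nodes(pts, cfg.field_size)
        assert ns.n_nodes == 0

    def test_erk_off_preset_enlarges_nodes(self):
        from erkwave import fixture_config

        base = SimConfig(field_size=(1200.0, 1200.0), n_frames=1, rng_seed=81)
        gt_base = simulate(base)
        ns_base = detect_nodes(
            gt_base.cells[gt_base.cells["frame"] == 0][["x_um", "y_um"]].to_numpy(),
            base.field_size)
        meki = fixture_config("fig6_meki", seed=81)
        gt_meki = simulate(meki)
        assert (gt_meki.cells["E"] == 0.0).all()
        ns_meki = detect_nodes(
            gt_meki.cells[gt_meki.cells["frame"] == 0][["x_um", "y_um"]].to_numpy(),
            meki.field_size)
        assert ns_meki.total_area_um2 > ns_base.total_area_um2
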