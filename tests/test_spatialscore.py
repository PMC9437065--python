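"""Proximity network, patch scores, stratification and pixel immunoscores."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import svscore as s
from svscore.datamodel import CellTable, pair_key

from conftest import random_typed_cells

TYPES = ("Tumor", "Stroma", "CD8", "M1", "M2")


def cells_at(points_types):
    """Cell table from explicit (x_um, y_um, type) triples."""
    panel = s.default_panel()
    n = len(points_types)
    df = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "centroid_x_px": [p[0] for p in points_types],
        "centroid_y_px": [p[1] for p in points_types],
        "centroid_x_um": [p[0] for p in points_types],
        "centroid_y_um": [p[1] for p in points_types],
        "area_px": np.ones(n, int),
    })
    for name in panel.names:
        df[f"mean_{name}"] = 0.0
    table = CellTable(df=df, marker_names=panel.names)
    table.df["cell_type"] = [p[2] for p in points_types]
    return table


def brute_force_edges(table, radius):
    xy = table.centroids_um
    ids = table.df["cell_id"].to_numpy()
    out = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if math.dist(xy[i], xy[j]) <= radius:
                out.add(frozenset((int(ids[i]), int(ids[j]))))
    return out


class TestProximityGraph:
    def test_boundary_distance_is_inclusive(self):
        g = s.build_proximity_graph(
            cells_at([(0, 0, "Tumor"), (30.0, 0, "CD8")]), radius_um=30)
        assert g.n_edges == 1

    def test_just_beyond_radius_not_connected(self):
        g = s.build_proximity_graph(
            cells_at([(0, 0, "Tumor"), (30.1, 0, "CD8")]), radius_um=30)
        assert g.n_edges == 0

    def test_single_cell_graph_has_no_edges(self):
        g = s.build_proximity_graph(cells_at([(5, 5, "CD8")]))
        assert g.n_nodes == 1 and g.n_edges == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_spatial_index_equals_bruteforce_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        table = random_typed_cells(rng, 200, size_um=300.0)
        g = s.build_proximity_graph(table, radius_um=30)
        got = {frozenset(e) for e in g.graph.edges}
        assert got == brute_force_edges(table, 30)

    def test_untyped_cells_rejected(self):
        table = cells_at([(0, 0, "Tumor")])
        table.df["cell_type"] = pd.NA
        with pytest.raises(ValueError, match="untyped"):
            s.build_proximity_graph(table)


class TestPatchStats:
    def test_clustered_patch_example_links_and_score(self):
        # 3 tumor cells + 1 CD8, all mutually within 30 um, one patch
        table = cells_at([(5, 5, "Tumor"), (10, 5, "Tumor"),
                          (5, 10, "Tumor"), (10, 10, "CD8")])
        g = s.build_proximity_graph(table, radius_um=30)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=25,
                                      type_order=TYPES)
        assert stats.grid_shape == (1, 1)
        assert stats.link_counts[("Tumor", "CD8")][0, 0] == 3
        assert stats.link_counts[("CD8", "Tumor")][0, 0] == 3
        key = pair_key("Tumor", "CD8", TYPES)
        assert stats.pair_scores[key][0, 0] == pytest.approx(1.0)

    def test_empty_patches_have_zero_density_and_scores(self):
        table = cells_at([(5, 5, "Tumor")])
        g = s.build_proximity_graph(table)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=100,
                                      type_order=TYPES)
        assert stats.grid_shape == (4, 4)
        empty = stats.n_cell == 0
        for t in TYPES:
            assert np.all(stats.densities[t][empty] == 0)
        for grid in stats.pair_scores.values():
            assert np.all(grid[empty] == 0)

    def test_density_formula(self):
        table = cells_at([(1, 1, "Tumor"), (2, 2, "Tumor"),
                          (3, 3, "Tumor"), (4, 4, "CD8")])
        g = s.build_proximity_graph(table)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=25,
                                      type_order=TYPES)
        assert stats.densities["Tumor"][0, 0] == pytest.approx(0.75)
        assert stats.densities["CD8"][0, 0] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(4))
    def test_link_conservation_against_whole_graph(self, seed):
        """Sum of L_i,A->B over patches equals the graph-wide directed
        A->B link count, for every ordered pair."""
        rng = np.random.default_rng(100 + seed)
        table = random_typed_cells(rng, 150, size_um=200.0)
        g = s.build_proximity_graph(table, radius_um=30)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=200,
                                      type_order=TYPES)
        types = g.node_types()
        for a, b in itertools.product(TYPES, repeat=2):
            total = sum(1 for u, v in g.graph.edges
                        for (x, y) in ((u, v), (v, u))
                        if types[x] == a and types[y] == b)
            assert stats.link_counts[(a, b)].sum() == total, (a, b)

    @pytest.mark.parametrize("seed", range(4))
    def test_densities_sum_to_one_and_scores_bounded(self, seed):
        rng = np.random.default_rng(200 + seed)
        table = random_typed_cells(rng, 120, size_um=200.0)
        g = s.build_proximity_graph(table)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=200,
                                      type_order=TYPES)
        nonempty = stats.n_cell > 0
        total_density = sum(stats.densities[t] for t in TYPES)
        assert np.allclose(total_density[nonempty], 1.0)
        assert np.all(total_density[~nonempty] == 0.0)
        for grid in stats.pair_scores.values():
            assert grid.min() >= 0.0 and grid.max() <= 1.0

    def test_pair_scores_symmetric_by_construction(self):
        rng = np.random.default_rng(5)
        table = random_typed_cells(rng, 80, size_um=150.0)
        g = s.build_proximity_graph(table)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=150,
                                      type_order=TYPES)
        for a, b in itertools.combinations(TYPES, 2):
            assert pair_key(a, b, TYPES) == pair_key(b, a, TYPES)
            assert pair_key(a, b, TYPES) in stats.pair_scores

    def test_invalid_patch_size_rejected(self):
        g = s.build_proximity_graph(cells_at([(0, 0, "CD8")]))
        with pytest.raises(ValueError):
            s.compute_patch_stats(g, patch_um=0, roi_size_um=100)


class TestRoiScores:
    def test_mean_of_nonempty_patch_scores_and_10x_scaling(self):
        # two occupied patches: one saturated CD8-Tumor pair, one inert
        table = cells_at([(5, 5, "Tumor"), (10, 10, "CD8"),
                          (80, 80, "Stroma"), (85, 85, "Stroma")])
        g = s.build_proximity_graph(table, radius_um=30)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=100,
                                      type_order=TYPES)
        report = s.roi_scores(stats)
        # CD8-Tumor: patch 1 scores 1.0, patch 2 scores 0 -> raw 0.5
        assert report.raw("CD8", "Tumor") == pytest.approx(0.5)
        assert report.scaled("CD8", "Tumor") == pytest.approx(5.0)

    def test_all_empty_patches_scores_zero_and_cold(self):
        table = cells_at([(5, 5, "Tumor")])
        g = s.build_proximity_graph(table)
        stats = s.compute_patch_stats(g, patch_um=25, roi_size_um=100,
                                      type_order=TYPES)
        # drop the one cell to fake a fully empty grid
        stats.n_cell[:] = 0
        report = s.roi_scores(stats)
        assert all(v == 0 for v in report.raw_scores.values())
        assert report.stratum == "cold"

    def test_inflamed_outranks_cold_synthetic(self, rules):
        scores = {}
        for arch in ("inflamed", "cold"):
            roi, mask, _ = s.generate_roi(arch, n_cells=300, size_um=400.0,
                                          seed=5)
            *_, report = s.score_roi(roi, mask, rules)
            scores[arch] = report.scaled("CD8", "Tumor")
        assert scores["inflamed"] > scores["cold"]

    def test_adding_cd8_near_all_patch_tumors_never_lowers_score(self):
        """Appending a CD8 cell adjacent to every tumor cell of its patch
        cannot decrease the ROI CD8-Tumor raw score."""
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(8):
            table = random_typed_cells(rng, 60, size_um=150.0)
            g = s.build_proximity_graph(table)
            before = s.roi_scores(
                s.compute_patch_stats(g, 25, 150, TYPES)).raw("CD8", "Tumor")
            # pick a patch holding tumor cells; drop the new CD8 cell at
            # their centroid, requiring it to reach every one of them
            df = table.df
            tum = df[df["cell_type"] == "Tumor"]
            patches = (tum["centroid_x_um"] // 25).astype(int) * 100 \
                + (tum["centroid_y_um"] // 25).astype(int)
            target = patches.mode().iloc[0]
            grp = tum[patches == target]
            x = grp["centroid_x_um"].mean()
            y = grp["centroid_y_um"].mean()
            d = np.hypot(grp["centroid_x_um"] - x, grp["centroid_y_um"] - y)
            if d.max() > 30:
                continue
            checked += 1
            new = df.iloc[[0]].copy()
            new["cell_id"] = df["cell_id"].max() + 1
            new[["centroid_x_um", "centroid_y_um"]] = (x, y)
            new[["centroid_x_px", "centroid_y_px"]] = (x, y)
            new["cell_type"] = "CD8"
            bigger = CellTable(df=pd.concat([df, new], ignore_index=True),
                               marker_names=table.marker_names)
            g2 = s.build_proximity_graph(bigger)
            after = s.roi_scores(
                s.compute_patch_stats(g2, 25, 150, TYPES)).raw("CD8", "Tumor")
            assert after >= before - 1e-12
        assert checked >= 4


class TestStratify:
    def test_paper_bin_examples(self):
        assert s.stratify_scores(8.0, 0.0, 0.0) == "inflamed"
        assert s.stratify_scores(1.0, 0.0, 0.0) == "cold"
        assert s.stratify_scores(4.0, 1.0, 2.0) == "suppressed"
        assert s.stratify_scores(4.0, 2.0, 1.0) == "inflamed"

    def test_half_open_bin_edges(self):
        assert s.stratify_scores(2.255, 0, 0) == "cold"
        assert s.stratify_scores(6.695, 0, 1) == "suppressed"
        assert s.stratify_scores(10.0, 0, 0) == "inflamed"
        assert s.stratify_scores(0.0, 0, 0) == "cold"

    def test_exhaustive_rule_table(self):
        """Enumerate a grid over [0, 10]^3 against an independently coded
        rule table."""
        lows, mids = 2.255, 6.695
        for cd8 in np.linspace(0, 10, 21):
            for m1 in (0.0, 5.0, 10.0):
                for m2 in (0.0, 5.0, 10.0):
                    got = s.stratify_scores(cd8, m1, m2)
                    if cd8 <= lows:
                        expect = "cold"
                    elif cd8 <= mids:
                        expect = "suppressed" if m2 >= m1 else "inflamed"
                    else:
                        expect = "inflamed"
                    assert got == expect, (cd8, m1, m2)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            s.stratify_scores(11.0, 0, 0)


class TestPixelScores:
    def test_grid_geometry_1500um_roi(self, rules):
        panel = s.default_panel()
        stack = np.zeros((len(panel), 1500, 1500))
        pmap = s.classify_patches_pixel(stack, rules, panel=panel, patch_px=5)
        assert pmap.grid.shape == (300, 300)
        assert pmap.n_patches == 90_000

    def test_zero_patch_is_background(self, panel, rules):
        pmap = s.classify_patches_pixel(np.zeros((len(panel), 10, 10)),
                                        rules, panel=panel, patch_px=5)
        assert np.all(pmap.grid == -1)

    def test_dominant_marker_wins_patch(self, panel, rules):
        stack = np.zeros((len(panel), 5, 5))
        stack[panel.index_of("CD8a")] = 0.5
        pmap = s.classify_patches_pixel(stack, rules, panel=panel, patch_px=5)
        names = [r.type_name for r in rules]
        assert pmap.type_grid()[0, 0] == "CD8"
        assert pmap.grid[0, 0] == names.index("CD8")

    def test_all_tumor_2x2_grid_adjacency(self, panel, rules):
        stack = np.zeros((len(panel), 10, 10))
        stack[panel.index_of("ECadherin")] = 1.0
        stack[panel.index_of("PanKeratin")] = 1.0
        pmap = s.classify_patches_pixel(stack, rules, panel=panel, patch_px=5)
        assert pmap.grid.shape == (2, 2)
        dens, scores = s.pixel_pair_scores(pmap)
        assert dens["Tumor"] == pytest.approx(1.0)
        # 2x2 grid has 4 adjacent pairs under 4-connectivity, all Tumor-Tumor
        key = pair_key("Tumor", "Tumor", pmap.type_order)
        assert scores[key] == pytest.approx(1.0)

    def test_checkerboard_immunoscore(self, panel, rules):
        stack = np.zeros((len(panel), 10, 10))
        t = np.array([[1, 0], [0, 1]], bool)
        big = np.kron(t, np.ones((5, 5), bool))
        stack[panel.index_of("ECadherin")][big] = 1.0
        stack[panel.index_of("PanKeratin")][big] = 1.0
        stack[panel.index_of("CD8a")][~big] = 1.0
        pmap = s.classify_patches_pixel(stack, rules, panel=panel, patch_px=5)
        dens, scores = s.pixel_pair_scores(pmap)
        assert scores[pair_key("Tumor", "CD8", pmap.type_order)] == 1.0
        assert scores[pair_key("Tumor", "Tumor", pmap.type_order)] == 0.0
        assert scores[pair_key("CD8", "CD8", pmap.type_order)] == 0.0

    def test_single_patch_grid_has_no_neighbors(self, panel, rules):
        pmap = s.classify_patches_pixel(np.zeros((len(panel), 5, 5)),
                                        rules, panel=panel, patch_px=5)
        _, scores = s.pixel_pair_scores(pmap)
        assert all(v == 0.0 for v in scores.values())

    def test_densities_with_background_sum_to_one(self, panel, rules):
        rng = np.random.default_rng(12)
        stack = rng.uniform(0, 1, size=(len(panel), 30, 30))
        pmap = s.classify_patches_pixel(stack, rules, panel=panel, patch_px=5)
        dens, _ = s.pixel_pair_scores(pmap)
        assert sum(dens.values()) == pytest.approx(1.0)

    def test_invalid_patch_px_rejected(self, panel, rules):
        with pytest.raises(ValueError):
            s.classify_patches_pixel(np.zeros((len(panel), 5, 5)), rules,
                                     panel=panel, patch_px=0)


class TestM2M1Ratio:
    def test_simple_ratio(self):
        assert s.m2_m1_ratio({"M2": 10, "M1": 5}) == pytest.approx(2.0)

    def test_zero_m2(self):
        assert s.m2_m1_ratio({"M2": 0, "M1": 5}) == 0.0

    def test_zero_m1_warns_and_returns_inf(self):
        with pytest.warns(RuntimeWarning, match="M2/M1"):
            assert s.m2_m1_ratio({"M2": 3, "M1": 0}) == np.inf
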