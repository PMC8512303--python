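"""Label-image measurements, contact rules, angles and asymmetry calls."""

import numpy as np
import pandas as pd
import pytest
import shapely.geometry as sg
from hypothesis import given, strategies as st
from scipy.spatial.distance import cdist

from acdkit import morphometry as morph
from acdkit.synthetic import TissueSpec, generate_epidermis
from conftest import brute_force_components


class TestMeasureCells:
    def test_area_is_pixel_count_times_pixel_area(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:15, 5:15] = 1   # 10x10 square
        labels[labels == 0] = 2
        cells = morph.measure_cells(labels, pixel_size_um=1.0)
        assert cells.set_index("cell_id").loc[1, "area_um2"] == 100.0

    def test_small_cell_threshold_is_strict(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[0:10, 0:12] = 1    # 120 px
        labels[20:30, 0:12] = 2
        labels[20:30, 11] = 0
        labels[20:30, 20:31] = 2  # total 110+110... rebuild cleanly below
        labels = np.zeros((40, 40), dtype=int)
        labels[:, :] = 3
        labels[0:10, 0:12] = 1          # exactly 120 um^2 at 1 um pixels
        labels[20:30, 0:12] = 2
        labels[25, 5] = 3               # 119 um^2
        cells = morph.measure_cells(labels, 1.0).set_index("cell_id")
        assert cells.loc[1, "area_um2"] == 120.0 and not cells.loc[1, "is_small"]
        assert cells.loc[2, "area_um2"] == 119.0 and cells.loc[2, "is_small"]

    def test_small_count_matches_generator_truth(self):
        spec = TissueSpec(field_width_um=200, field_height_um=200, n_cells=120,
                          small_cell_fraction=0.3, seed=21)
        labels, truth = generate_epidermis(spec)
        cells = morph.measure_cells(labels, 1.0)
        assert cells.is_small.sum() == truth.is_small.sum() == 36
        merged = cells.merge(truth, on="cell_id", suffixes=("", "_t"))
        assert (merged.is_small == merged.is_small_t).all()


class TestAdjacency:
    def test_shared_edge_and_corner_convention(self):
        labels = np.array([[1, 1, 2],
                           [1, 1, 2],
                           [3, 3, 4]])
        g = morph.build_adjacency(labels)
        assert g.has_edge(1, 2) and g.has_edge(1, 3) and g.has_edge(2, 4)
        # 1 and 4 touch only at a corner: not in contact (4-connectivity)
        assert not g.has_edge(1, 4)

    def test_matches_all_pixel_pairs_oracle(self):
        """Contact graph equals the brute-force oracle comparing every pixel
        of one cell against every pixel of the other."""
        spec = TissueSpec(field_width_um=130, field_height_um=130, n_cells=50,
                          pixel_size_um=2.0, small_cell_fraction=0.1, seed=13)
        labels, _ = generate_epidermis(spec)
        g = morph.build_adjacency(labels)
        coords = {int(i): np.argwhere(labels == i) for i in np.unique(labels)}
        ids = sorted(coords)
        for i_pos, a in enumerate(ids):
            for b in ids[i_pos + 1:]:
                d = cdist(coords[a], coords[b], metric="cityblock").min()
                assert g.has_edge(a, b) == (d == 1.0)


class TestClusters:
    def _tissue(self, seed):
        spec = TissueSpec(field_width_um=170, field_height_um=170, n_cells=90,
                          small_cell_fraction=0.12,
                          planted_clusters=[(4, 1)], seed=seed)
        labels, truth = generate_epidermis(spec)
        cells = morph.measure_cells(labels, 1.0)
        return labels, truth, cells

    def test_planted_fraction(self, small_tissue):
        _, labels, truth = small_tissue
        cells = morph.measure_cells(labels, 1.0)
        report = morph.find_small_cell_clusters(
            cells, morph.build_adjacency(labels))
        n_small_truth = int(truth.is_small.sum())
        assert report.n_small == n_small_truth
        assert report.n_small_in_clusters == 8   # two planted 4-cell clusters
        assert report.fraction_in_clusters == pytest.approx(8 / n_small_truth)

    def test_three_cell_chain_is_not_a_cluster(self):
        morphs = pd.DataFrame({"cell_id": [1, 2, 3, 4],
                               "is_small": [True, True, True, False],
                               "type": "unknown"})
        import networkx as nx
        g = nx.Graph([(1, 2), (2, 3), (3, 4)])
        report = morph.find_small_cell_clusters(morphs, g)
        assert report.clusters == []
        assert report.n_small == 3 and report.n_small_in_clusters == 0

    def test_exactly_four_cells_is_a_cluster(self):
        morphs = pd.DataFrame({"cell_id": [1, 2, 3, 4],
                               "is_small": True, "type": "unknown"})
        import networkx as nx
        g = nx.Graph([(1, 2), (2, 3), (3, 4)])
        report = morph.find_small_cell_clusters(morphs, g)
        assert report.clusters == [{1, 2, 3, 4}]
        assert report.fraction_in_clusters == 1.0

    def test_no_small_cells_fraction_zero_by_convention(self):
        morphs = pd.DataFrame({"cell_id": [1, 2], "is_small": False,
                               "type": "unknown"})
        import networkx as nx
        report = morph.find_small_cell_clusters(morphs, nx.Graph([(1, 2)]))
        assert report.fraction_in_clusters == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_component_oracle(self, seed):
        labels, _, cells = self._tissue(seed)
        g = morph.build_adjacency(labels)
        report = morph.find_small_cell_clusters(cells, g)
        oracle = brute_force_components(
            cells.loc[cells.is_small, "cell_id"].astype(int),
            list(g.edges), 4)
        assert sorted(report.clusters, key=min) == oracle


class TestStomata:
    def _frame(self, types):
        return pd.DataFrame({"cell_id": list(types), "is_small": False,
                             "type": [types[k] for k in types]})

    def test_one_adjacent_pair_among_ten(self):
        import networkx as nx
        types = {i: "stoma" for i in range(1, 11)}
        g = nx.Graph()
        g.add_nodes_from(types)
        g.add_edge(1, 2)
        res = morph.count_stomatal_clusters(self._frame(types), g)
        assert (res.n_stomata, res.n_in_contact) == (10, 2)
        assert res.percent_clustered == pytest.approx(20.0)

    def test_all_isolated_gives_zero_percent(self):
        import networkx as nx
        types = {1: "stoma", 2: "stoma", 3: "pavement"}
        g = nx.Graph([(1, 3), (3, 2)])
        res = morph.count_stomatal_clusters(self._frame(types), g)
        assert res.percent_clustered == 0.0

    def test_no_stomata_percent_absent(self):
        import networkx as nx
        res = morph.count_stomatal_clusters(self._frame({1: "pavement"}),
                                            nx.Graph())
        assert res.percent_clustered is None


class TestSpacingAngle:
    @pytest.mark.parametrize("pore,plane,expected", [
        (0, 0, 0), (10, 100, 90), (170, 10, 20), (45, 45, 0), (0, 90, 90),
    ])
    def test_hand_computed_cases(self, pore, plane, expected):
        assert morph.spacing_angle(pore, plane) == pytest.approx(expected)

    @given(a=st.floats(0, 360), b=st.floats(0, 360))
    def test_symmetric_and_axis_periodic(self, a, b):
        alpha = morph.spacing_angle(a, b)
        assert 0.0 <= alpha <= 90.0
        assert alpha == pytest.approx(morph.spacing_angle(b, a))
        assert alpha == pytest.approx(morph.spacing_angle(a + 180.0, b),
                                      abs=1e-9)


class TestCumulativeCurve:
    def test_all_zero_angles(self):
        assert (morph.cumulative_angle_curve([0.0, 0.0]) == 1.0).all()

    def test_three_point_curve(self):
        curve = morph.cumulative_angle_curve([0.0, 45.0, 90.0])
        assert curve[44] == pytest.approx(1 / 3)
        assert curve[45] == pytest.approx(2 / 3)
        assert curve[90] == pytest.approx(1.0)

    def test_monotone_and_terminal(self, rng):
        curve = morph.cumulative_angle_curve(rng.uniform(0, 90, 500))
        assert (np.diff(curve) >= 0).all()
        assert curve[-1] == 1.0

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            morph.cumulative_angle_curve([])
        with pytest.raises(ValueError):
            morph.cumulative_angle_curve([95.0])


class TestSizeAsymmetry:
    def test_typical_half_area_meristemoid(self):
        res = morph.size_asymmetry(1, {"m": 50.0, "s": 100.0},
                                   crescent_daughter_id="s")
        assert res.ratio == pytest.approx(0.5)
        assert res.reversed is False

    def test_crescent_in_smaller_daughter_is_reversed(self):
        res = morph.size_asymmetry(1, {"c": 60.0, "s": 100.0},
                                   crescent_daughter_id="c")
        assert res.reversed is True
        assert res.slgc_area_um2 == 60.0   # fate follows the crescent

    def test_equal_areas_not_reversed(self):
        res = morph.size_asymmetry(1, {"a": 80.0, "b": 80.0},
                                   crescent_daughter_id="a")
        assert res.reversed is False

    def test_missing_crescent_annotation(self):
        res = morph.size_asymmetry(1, {"a": 50.0, "b": 100.0})
        assert res.reversed is None
        assert res.ratio == pytest.approx(0.5)


class TestNuclearOffset:
    def test_centred_nucleus_is_zero(self):
        disk = sg.Point(0, 0).buffer(1.0, quad_segs=256)
        assert morph.nuclear_offset(disk, (0.0, 0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_disk_closed_form(self):
        disk = sg.Point(0, 0).buffer(1.0, quad_segs=256)
        assert morph.nuclear_offset(disk, (0.8, 0.0)) == pytest.approx(
            0.8, abs=1e-3)

    def test_halfway_along_arbitrary_ray(self):
        rect = sg.Polygon([(0, 0), (4, 0), (4, 2), (0, 2)])
        # centroid (2, 1); boundary along +x at distance 2; halfway = (3, 1)
        assert morph.nuclear_offset(rect, (3.0, 1.0)) == pytest.approx(0.5)

    def test_nucleus_outside_cell_rejected(self):
        disk = sg.Point(0, 0).buffer(1.0)
        with pytest.raises(ValueError):
            morph.nuclear_offset(disk, (2.0, 0.0))

    def test_mask_version_invariant_to_rigid_motion(self):
        mask = np.zeros((60, 60), dtype=bool)
        yy, xx = np.mgrid[0:60, 0:60]
        mask[(yy - 25) ** 2 + (xx - 20) ** 2 <= 144] = True
        off0 = morph.nuclear_offset(mask, (26.0, 25.0))   # (col,row)
        # translate by (+8, +10)
        mask_t = np.zeros_like(mask)
        mask_t[(yy - 35) ** 2 + (xx - 28) ** 2 <= 144] = True
        off_t = morph.nuclear_offset(mask_t, (34.0, 35.0))
        assert off_t == pytest.approx(off0, abs=0.02)
        # rotate 90 degrees
        mask_r = np.rot90(mask).copy()
        crow, ccol = 25, 20
        # (col,row)=(26,25) maps under rot90 to (row, n-1-col)
        off_r = morph.nuclear_offset(mask_r, (25.0, 59 - 26.0))
        assert off_r == pytest.approx(off0, abs=0.02)
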