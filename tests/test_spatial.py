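"""kNN graph, extrinsic profiles and the intrinsic/extrinsic blend."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import spotdeconv as sd


def _st(coords, counts=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if counts is None:
        counts = np.random.default_rng(0).poisson(3.0, (15, n))
    return sd.SpatialDataset(counts=counts,
                             gene_ids=[f"g{i:02d}" for i in range(counts.shape[0])],
                             spot_ids=[f"s{i}" for i in range(n)],
                             coords=coords)


class TestSpatialGraph:
    def test_unit_square_geometry(self):
        st = _st([(0, 0), (1, 0), (0, 1), (1, 1)])
        graph = sd.build_spatial_graph(st, k=2)
        # each corner's 2 nearest are the edge-adjacent corners, not diagonal
        expected = {0: {1, 2}, 1: {0, 3}, 2: {0, 3}, 3: {1, 2}}
        for i, nbrs in expected.items():
            assert set(graph.neighbor_ids[i]) == nbrs
            np.testing.assert_allclose(graph.neighbor_dists[i], 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        st = _st(rng.random((100, 2)))
        k = 5
        graph = sd.build_spatial_graph(st, k=k)
        dists = cdist(st.coords, st.coords)
        for i in range(100):
            order = sorted(range(100), key=lambda j: (dists[i, j], j))
            expected = [j for j in order if j != i][:k]
            assert graph.neighbor_ids[i].tolist() == expected

    def test_duplicate_coordinates_tie_break_by_index(self):
        st = _st([(0, 0), (0, 0), (5, 5)])
        graph = sd.build_spatial_graph(st, k=1)
        assert graph.neighbor_ids[0, 0] == 1
        assert graph.neighbor_ids[1, 0] == 0

    def test_self_never_neighbour_and_rows_sorted(self):
        rng = np.random.default_rng(2)
        st = _st(rng.random((30, 2)))
        graph = sd.build_spatial_graph(st, k=6)
        for i in range(30):
            assert i not in graph.neighbor_ids[i]
            assert (np.diff(graph.neighbor_dists[i]) >= 0).all()

    def test_k_too_large_rejected(self):
        st = _st([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="k"):
            sd.build_spatial_graph(st, k=2)


class TestExtrinsicProfiles:
    def test_k1_equals_nearest_neighbour_counts(self):
        st = _st([(0, 0), (1, 0), (10, 0)])
        graph = sd.build_spatial_graph(st, k=1)
        ext = sd.build_extrinsic_profiles(st, graph)
        np.testing.assert_array_equal(ext[:, 0], st.counts[:, 1])
        np.testing.assert_array_equal(ext[:, 1], st.counts[:, 0])

    def test_homogeneous_spots_give_k_times_counts(self):
        c = np.arange(15)
        counts = np.tile(c[:, None], (1, 5))
        st = _st(np.random.default_rng(3).random((5, 2)), counts=counts)
        graph = sd.build_spatial_graph(st, k=3)
        ext = sd.build_extrinsic_profiles(st, graph)
        np.testing.assert_array_equal(ext, np.tile(3 * c[:, None], (1, 5)))

    def test_column_totals_conserved_from_graph(self):
        rng = np.random.default_rng(4)
        st = _st(rng.random((20, 2)))
        graph = sd.build_spatial_graph(st, k=4)
        ext = sd.build_extrinsic_profiles(st, graph)
        totals = st.counts.sum(axis=0)
        for i in range(20):
            assert ext[:, i].sum() == totals[graph.neighbor_ids[i]].sum()


class TestRegularize:
    @pytest.fixture
    def blend_inputs(self):
        rng = np.random.default_rng(5)
        intrinsic = rng.dirichlet(np.ones(3), size=12)
        extrinsic = rng.dirichlet(np.ones(3), size=12)
        st_norm = rng.random((12, 15))
        ext_norm = st_norm + 0.1 * rng.random((12, 15))
        return intrinsic, extrinsic, st_norm, ext_norm

    def test_lambda_zero_is_bit_exact_identity(self, blend_inputs):
        intrinsic, extrinsic, st_norm, ext_norm = blend_inputs
        cfg = sd.RegularizationConfig(lambda_max=0.0)
        res = sd.regularize(intrinsic, extrinsic, st_norm, ext_norm, cfg)
        assert (res.regularized_props == intrinsic).all()
        assert (res.lambda_per_spot == 0).all()

    def test_identical_profiles_get_lambda_max(self):
        rng = np.random.default_rng(6)
        intrinsic = rng.dirichlet(np.ones(3), size=4)
        extrinsic = rng.dirichlet(np.ones(3), size=4)
        norm = rng.random((4, 10))
        ext_norm = norm.copy()
        ext_norm[3] = rng.random(10) * 5  # one dissimilar spot anchors d=1
        cfg = sd.RegularizationConfig(lambda_max=0.5)
        res = sd.regularize(intrinsic, extrinsic, norm, ext_norm, cfg)
        lam = res.lambda_per_spot
        np.testing.assert_allclose(lam[:3], 0.5, atol=1e-12)
        expected = 0.5 * intrinsic[:3] + 0.5 * extrinsic[:3]
        np.testing.assert_allclose(res.regularized_props[:3], expected)
        # the maximally dissimilar spot is untouched
        assert lam[3] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.regularized_props[3], intrinsic[3])

    def test_rows_stay_on_simplex_and_segment(self, blend_inputs):
        intrinsic, extrinsic, st_norm, ext_norm = blend_inputs
        res = sd.regularize(intrinsic, extrinsic, st_norm, ext_norm)
        reg = res.regularized_props
        np.testing.assert_allclose(reg.sum(axis=1), 1.0, atol=1e-9)
        lam = res.lambda_per_spot[:, None]
        np.testing.assert_allclose(
            reg, (1 - lam) * intrinsic + lam * extrinsic, atol=1e-12)

    def test_lambda_monotone_in_distance(self, blend_inputs):
        intrinsic, extrinsic, st_norm, ext_norm = blend_inputs
        res = sd.regularize(intrinsic, extrinsic, st_norm, ext_norm)
        order = np.argsort(res.intrinsic_extrinsic_dist)
        lam_sorted = res.lambda_per_spot[order]
        assert (np.diff(lam_sorted) <= 1e-12).all()


class TestSmoothing:
    def _roughness(self, props, graph):
        diffs = []
        for i in range(props.shape[0]):
            for j in graph.neighbor_ids[i]:
                diffs.append(np.abs(props[i] - props[j]).mean())
        return np.mean(diffs)

    def test_regularization_does_not_increase_roughness(
            self, small_config, small_ref, two_region_spatial, trained_model):
        st, _ = two_region_spatial
        graph = sd.build_spatial_graph(st, k=4)
        ext_counts = sd.build_extrinsic_profiles(st, graph)
        st_norm = trained_model.prepare(st.counts, st.gene_ids)
        ext_norm = trained_model.prepare(ext_counts, st.gene_ids)
        intrinsic = trained_model.net.predict(st_norm)
        extrinsic = trained_model.net.predict(ext_norm)
        res = sd.regularize(intrinsic, extrinsic, st_norm, ext_norm,
                            sd.RegularizationConfig(lambda_max=0.5))
        before = self._roughness(intrinsic, graph)
        after = self._roughness(res.regularized_props, graph)
        assert after <= before + 1e-12


class TestDistanceMap:
    def test_row_count_and_homogeneous_distances(self):
        rng = np.random.default_rng(8)
        intrinsic = rng.dirichlet(np.ones(3), size=6)
        norm = np.tile(rng.random(10), (6, 1))
        res = sd.regularize(intrinsic, intrinsic.copy(), norm, norm.copy())
        coords = rng.random((6, 2))
        table = sd.intrinsic_extrinsic_distance_map(res, coords)
        assert len(table) == 6
        assert table["distance"].nunique() == 1

    def test_boundary_spots_have_largest_distances(
            self, small_config, small_ref, two_region_spatial, trained_model):
        st, _ = two_region_spatial
        graph = sd.build_spatial_graph(st, k=4)
        ext_counts = sd.build_extrinsic_profiles(st, graph)
        st_norm = trained_model.prepare(st.counts, st.gene_ids)
        ext_norm = trained_model.prepare(ext_counts, st.gene_ids)
        intrinsic = trained_model.net.predict(st_norm)
        extrinsic = trained_model.net.predict(ext_norm)
        res = sd.regularize(intrinsic, extrinsic, st_norm, ext_norm,
                            spot_ids=st.spot_ids)
        table = sd.intrinsic_extrinsic_distance_map(res, st.coords)
        # region boundary runs down the middle column of the 8x8 grid
        cols = st.coords[:, 0]
        mid = np.abs(cols - cols.mean()) <= 1.0
        boundary_mean = table.loc[mid, "distance"].mean()
        interior_mean = table.loc[~mid, "distance"].mean()
        assert boundary_mean > interior_mean
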