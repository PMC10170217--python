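"""Surface clusters, permutation pruning and flat-map distance geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import magmap.surface as sf
from magmap.simulate import make_patch
from magmap.surface import (
    ROIDefinition,
    bin_distance,
    cluster_permutation_prune,
    connected_clusters,
    normalized_distance,
    orient_progression,
    project_to_polyline,
)


def _flood_fill_clusters(mask, faces):
    """Brute-force oracle: BFS over shared-edge adjacency."""
    n = len(mask)
    adj = {i: set() for i in range(n)}
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (c, a)):
            adj[u].add(v)
            adj[v].add(u)
    seen = set()
    clusters = []
    for start in np.flatnonzero(mask):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in adj[u] if mask[v] and v not in comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return set(clusters)


class TestConnectedClusters:
    def test_empty_mask(self, grid_patch):
        patch, _ = grid_patch
        assert connected_clusters(np.zeros(patch.n_vertices, bool), patch.faces) == []

    def test_full_mask_single_cluster(self, grid_patch):
        patch, _ = grid_patch
        clusters = connected_clusters(np.ones(patch.n_vertices, bool), patch.faces)
        assert len(clusters) == 1
        assert len(clusters[0]) == patch.n_vertices

    def test_two_nonadjacent_vertices_are_singletons(self, grid_patch):
        patch, _ = grid_patch
        mask = np.zeros(patch.n_vertices, bool)
        mask[[0, 55]] = True
        clusters = connected_clusters(mask, patch.faces)
        assert sorted(map(len, clusters)) == [1, 1]

    def test_matches_flood_fill_oracle(self, grid_patch, rng):
        patch, _ = grid_patch
        mask = rng.random(patch.n_vertices) < 0.3
        ours = {frozenset(c.tolist()) for c in connected_clusters(mask, patch.faces)}
        assert ours == _flood_fill_clusters(mask, patch.faces)


class TestClusterPermutation:
    def test_giant_cluster_survives(self):
        patch, _ = make_patch(32)  # ~1000 vertices
        mask = patch.flat_coords[:, 0] < 16  # a solid half of the patch
        pruned, min_size = cluster_permutation_prune(mask, patch.faces, seed=0)
        assert pruned.sum() == mask.sum()
        assert min_size == mask.sum()

    def test_scattered_singletons_pruned(self, grid_patch):
        patch, _ = grid_patch
        mask = np.zeros(patch.n_vertices, bool)
        mask[[0, 33, 66, 99]] = True  # isolated vertices
        pruned, min_size = cluster_permutation_prune(mask, patch.faces, seed=0)
        assert not pruned.any()
        assert min_size == 0

    def test_alpha_one_prunes_nothing(self, grid_patch, rng):
        patch, _ = grid_patch
        mask = rng.random(patch.n_vertices) < 0.2
        pruned, _ = cluster_permutation_prune(mask, patch.faces, alpha=1.0, seed=0)
        assert (pruned == mask).all()

    def test_low_n_perm_warns(self, grid_patch):
        patch, _ = grid_patch
        mask = np.zeros(patch.n_vertices, bool)
        mask[0] = True
        with pytest.warns(UserWarning):
            cluster_permutation_prune(mask, patch.faces, n_perm=50, seed=0)

    def test_full_mask_rejected(self, grid_patch):
        patch, _ = grid_patch
        with pytest.raises(ValueError):
            cluster_permutation_prune(np.ones(patch.n_vertices, bool), patch.faces)

    def test_deterministic_given_seed(self, grid_patch, rng):
        patch, _ = grid_patch
        mask = rng.random(patch.n_vertices) < 0.3
        a, _ = cluster_permutation_prune(mask, patch.faces, seed=5)
        b, _ = cluster_permutation_prune(mask, patch.faces, seed=5)
        assert (a == b).all()


class TestPolylineProjection:
    POLY = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])

    def test_point_on_polyline_projects_to_itself(self):
        assert np.allclose(project_to_polyline([0.5, 0.0], self.POLY), [0.5, 0.0])

    def test_tie_broken_by_first_segment(self):
        # (1 - eps, something) equidistant cases resolve to the earlier
        # segment; the corner point is shared, so probe a true tie
        p = project_to_polyline([0.5, 0.5], np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert np.allclose(p, [0.5, 0.0])  # first of several equidistant segments

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            project_to_polyline([0, 0], np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_matches_dense_sampling_oracle(self, rng):
        poly = rng.random((6, 2)) * 10
        # dense sample along every segment
        samples = np.concatenate([
            poly[i] + np.linspace(0, 1, 10000)[:, None] * (poly[i + 1] - poly[i])
            for i in range(len(poly) - 1)
        ])
        for _ in range(20):
            p = rng.random(2) * 12 - 1
            near = project_to_polyline(p, poly)
            d_ours = np.linalg.norm(near - p)
            d_oracle = np.linalg.norm(samples - p, axis=1).min()
            assert d_ours == pytest.approx(d_oracle, abs=1e-3)


class TestNormalizedDistance:
    ROI = ROIDefinition(
        vertices=np.arange(4),
        edge_a=np.array([[0.0, 0.0], [0.0, 4.0]]),
        edge_b=np.array([[5.0, 0.0], [5.0, 4.0]]),
    )

    def test_point_on_edge_a(self):
        assert normalized_distance([0.0, 2.0], self.ROI) == 0.0

    def test_midpoint_of_straight_strip(self):
        assert normalized_distance([2.5, 1.7], self.ROI) == pytest.approx(0.5)

    def test_hand_geometry_example(self):
        assert normalized_distance([2.0, 1.0], self.ROI) == pytest.approx(0.4)

    def test_rigid_motion_invariance(self, rng):
        angle = 0.7
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        shift = np.array([3.0, -8.0])
        roi2 = ROIDefinition(
            vertices=self.ROI.vertices,
            edge_a=self.ROI.edge_a @ rot.T + shift,
            edge_b=self.ROI.edge_b @ rot.T + shift,
        )
        for _ in range(20):
            v = rng.random(2) * np.array([5.0, 4.0])
            d1 = normalized_distance(v, self.ROI)
            d2 = normalized_distance(rot @ v + shift, roi2)
            assert d1 == pytest.approx(d2, abs=1e-9)

    def test_coincident_projections_rejected(self):
        roi = ROIDefinition(vertices=np.arange(1),
                            edge_a=np.array([[0.0, 0.0], [2.0, 0.0]]),
                            edge_b=np.array([[0.0, 0.0], [0.0, 2.0]]))
        with pytest.raises(ValueError):
            normalized_distance([0.0, 0.0], roi)


class TestBins:
    @pytest.mark.parametrize("d,label", [(0.0, 0), (1.0, 19), (0.05, 1),
                                         (0.049999, 0), (0.951, 19)])
    def test_bin_edges(self, d, label):
        assert bin_distance(d) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_distance(1.01)
        with pytest.raises(ValueError):
            bin_distance(-0.01)

    @given(hst.integers(0, 2**31 - 1))
    def test_bins_partition_the_roi(self, seed):
        d = np.random.default_rng(seed).random(200)
        labels = bin_distance(d)
        assert np.bincount(labels, minlength=20).sum() == 200
        assert labels.min() >= 0 and labels.max() <= 19


class TestOrientProgression:
    def test_increasing_unchanged(self):
        d = np.linspace(0, 1, 10)
        out, rev = orient_progression(d, 2 * d + 1)
        assert not rev
        assert np.allclose(out, d)

    def test_decreasing_reversed(self):
        d = np.linspace(0, 1, 10)
        out, rev = orient_progression(d, -2 * d + 1)
        assert rev
        assert np.allclose(out, 1 - d)

    def test_flat_neutral(self):
        d = np.linspace(0, 1, 10)
        out, rev = orient_progression(d, np.full(10, 3.0))
        assert not rev


class TestIO:
    def test_json_round_trip(self, grid_patch):
        patch, roi = grid_patch
        text = sf.patch_to_json(patch, roi)
        patch2, roi2 = sf.patch_from_json(text)
        assert np.array_equal(patch.faces, patch2.faces)
        assert np.allclose(patch.flat_coords, patch2.flat_coords)
        assert np.allclose(roi.edge_a, roi2.edge_a)

    def test_gifti_round_trip(self, grid_patch, tmp_path):
        patch, _ = grid_patch
        path = tmp_path / "patch.surf.gii"
        sf.patch_to_gifti(patch, path)
        patch2 = sf.patch_from_gifti(path)
        assert np.array_equal(patch.faces, patch2.faces)
        assert np.allclose(patch.flat_coords, patch2.flat_coords, atol=1e-6)
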