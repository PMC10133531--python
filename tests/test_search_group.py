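"""Hit search, grouping/extension semantics, and similarity scores."""

import numpy as np
import pytest

from surfaceid.mesh import RegionMask
from surfaceid.search import (Hit, HitGroup, all_vs_all, coverage_ratio_score,
                              find_hits, group_hits, joint_interface_score,
                              reciprocal_mean_score, InterfaceEntry)
from surfaceid.synthetic import make_icosphere


class TestFindHits:
    def test_self_match_contains_diagonal(self):
        rng = np.random.default_rng(0)
        desc = rng.normal(size=(20, 8)) * 10
        hits = find_hits(desc, desc, cutoff=3.5)
        diag = {(h.query_vertex, h.candidate_vertex) for h in hits
                if h.query_vertex == h.candidate_vertex}
        assert diag == {(i, i) for i in range(20)}

    def test_zero_cutoff_distinct_descriptors_empty(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 4))
        b = rng.normal(size=(10, 4))
        assert find_hits(a, b, cutoff=0.0) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(100, 6))
        b = rng.normal(size=(100, 6))
        hits = find_hits(a, b, cutoff=2.0)
        got = {(h.query_vertex, h.candidate_vertex) for h in hits}
        expected = set()
        for i in range(100):
            for j in range(100):
                if np.linalg.norm(a[i] - b[j]) <= 2.0:
                    expected.add((i, j))
        assert got == expected

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            find_hits(np.zeros((2, 4)), np.zeros((2, 5)))


def _cap_vertices(mesh, direction, n):
    """The n vertices closest to a direction on a sphere mesh."""
    u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    return np.argsort(-(u @ (direction / np.linalg.norm(direction))))[:n]


@pytest.fixture(scope="module")
def sphere():
    return make_icosphere(subdivisions=3, radius=9.0)


def _identity_hits(vertices, distance=0.1):
    return [Hit(int(v), int(v), distance) for v in vertices]


class TestGroupHits:
    def test_no_hits_gives_empty_list(self, sphere):
        assert group_hits([], sphere, sphere) == []

    def test_isolated_hit_is_excluded(self, sphere):
        cluster = _cap_vertices(sphere, np.array([0, 0, 1.0]), 8)
        lone = _cap_vertices(sphere, np.array([0, 0, -1.0]), 1)
        hits = _identity_hits(np.r_[cluster, lone])
        groups = group_hits(hits, sphere, sphere)
        assert len(groups) == 1
        assert lone[0] not in groups[0].query_vertices

    def test_dense_cluster_is_one_group(self, sphere):
        cluster = _cap_vertices(sphere, np.array([1.0, 0, 0]), 10)
        groups = group_hits(_identity_hits(cluster), sphere, sphere)
        assert len(groups) == 1
        assert set(groups[0].query_vertices) == set(int(v) for v in cluster)

    def test_two_separated_clusters_match_union_find_oracle(self, sphere):
        c1 = _cap_vertices(sphere, np.array([0, 0, 1.0]), 8)
        c2 = _cap_vertices(sphere, np.array([0, 0, -1.0]), 8)
        hits = _identity_hits(np.r_[c1, c2])
        groups = group_hits(hits, sphere, sphere, neighbor_radius=3.0)

        # brute-force union-find on the (query AND candidate) radius graph
        verts = [h.query_vertex for h in hits]
        parent = list(range(len(verts)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(verts)):
            for j in range(i + 1, len(verts)):
                dq = np.linalg.norm(sphere.vertices[verts[i]]
                                    - sphere.vertices[verts[j]])
                if dq <= 3.0:
                    parent[find(i)] = find(j)
        comp_sizes = {}
        for i in range(len(verts)):
            comp_sizes.setdefault(find(i), set()).add(verts[i])
        oracle_groups = [vs for vs in comp_sizes.values() if len(vs) >= 2]
        assert len(groups) == len(oracle_groups) == 2
        assert sorted(map(len, (g.query_vertices for g in groups))) == \
            sorted(map(len, oracle_groups))

    def test_each_hit_vertex_in_at_most_one_group(self, sphere):
        rng = np.random.default_rng(3)
        verts = rng.choice(sphere.n_vertices, size=60, replace=False)
        hits = [Hit(int(v), int(v), float(rng.uniform(0, 3)))
                for v in verts]
        groups = group_hits(hits, sphere, sphere)
        seen = set()
        for g in groups:
            for v in g.query_vertices:
                assert v not in seen
                seen.add(v)

    def test_extension_adds_nearby_surface(self, sphere):
        cluster = _cap_vertices(sphere, np.array([0, 1.0, 0]), 6)
        groups = group_hits(_identity_hits(cluster), sphere, sphere,
                            extension_radius=6.0)
        g = groups[0]
        assert g.extended
        assert len(g.query_vertices_extended) > len(g.query_vertices)
        assert set(g.query_vertices).issubset(set(g.query_vertices_extended))

    def test_min_group_size_filters_small_components(self, sphere):
        pair = _cap_vertices(sphere, np.array([1.0, 1.0, 0]), 2)
        big = _cap_vertices(sphere, np.array([-1.0, 0, 0]), 12)
        hits = _identity_hits(np.r_[pair, big])
        groups = group_hits(hits, sphere, sphere, min_group_size=5)
        assert len(groups) == 1
        assert len(groups[0].query_vertices) == 12


class TestScores:
    def test_perfect_match_scores_one(self, sphere):
        g = HitGroup(np.array([0, 1]), np.array([0, 1]),
                     [Hit(0, 0, 0.0), Hit(1, 1, 0.0)], ss=0.0)
        assert reciprocal_mean_score(g) == 1.0

    def test_mean_distance_one_scores_half(self, sphere):
        g = HitGroup(np.array([0, 1]), np.array([0, 1]),
                     [Hit(0, 0, 0.5), Hit(1, 1, 1.5)], ss=0.0)
        assert reciprocal_mean_score(g) == pytest.approx(0.5)

    def test_score_strictly_decreases_with_distance(self):
        base = [Hit(0, 0, 0.5), Hit(1, 1, 1.0)]
        g0 = HitGroup(np.array([0, 1]), np.array([0, 1]), base, ss=0.0)
        worse = [Hit(0, 0, 0.5), Hit(1, 1, 1.4)]
        g1 = HitGroup(np.array([0, 1]), np.array([0, 1]), worse, ss=0.0)
        assert reciprocal_mean_score(g1) < reciprocal_mean_score(g0)

    def test_empty_group_raises(self):
        g = HitGroup(np.array([]), np.array([]), [], ss=0.0)
        with pytest.raises(ValueError):
            reciprocal_mean_score(g)

    def test_joint_score_is_exact_product(self):
        assert joint_interface_score(1.0, 1.0) == 1.0
        assert joint_interface_score(0.8, 0.5) == pytest.approx(0.4)

    def test_joint_score_symmetric_under_role_swap(self):
        assert joint_interface_score(0.7, 0.3) == \
            joint_interface_score(0.3, 0.7)

    def test_joint_score_bounded_by_factors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0.01, 1.0, size=2)
            assert joint_interface_score(a, b) <= min(a, b) + 1e-15


class TestCoverageRatio:
    def _mask(self, mesh, n):
        flags = np.zeros(mesh.n_vertices, dtype=bool)
        flags[:n] = True
        return RegionMask(mesh.mesh_id, flags, 3.5)

    def _group_covering(self, verts):
        v = np.asarray(verts)
        return HitGroup(v, v, [Hit(int(x), int(x), 0.1) for x in v], ss=0.5,
                        query_vertices_extended=v,
                        candidate_vertices_extended=v)

    def test_full_coverage(self, sphere):
        mask = self._mask(sphere, 10)
        g = self._group_covering(np.arange(10))
        assert coverage_ratio_score(mask, [g]) == 1.0

    def test_no_groups_scores_zero(self, sphere):
        assert coverage_ratio_score(self._mask(sphere, 10), []) == 0.0

    def test_hand_counted_partial_coverage(self, sphere):
        mask = self._mask(sphere, 10)
        g = self._group_covering([0, 1, 2])    # 3 of 10
        assert coverage_ratio_score(mask, [g]) == pytest.approx(0.3)

    def test_monotone_in_group_set(self, sphere):
        mask = self._mask(sphere, 10)
        g1 = self._group_covering([0, 1])
        g2 = self._group_covering([5, 6, 7])
        assert coverage_ratio_score(mask, [g1, g2]) >= \
            coverage_ratio_score(mask, [g1])


class TestAllVsAll:
    def _entry(self, mesh, name, offset=0.0, n_mask=40):
        """Interface whose descriptors are the (offset) vertex coords —
        identical offsets give identical descriptor sets."""
        flags = np.zeros(mesh.n_vertices, dtype=bool)
        ids = _cap_vertices(mesh, np.array([0, 0, 1.0]), n_mask)
        flags[ids] = True
        desc = mesh.vertices[ids] + offset
        return InterfaceEntry(mesh=mesh, mask=RegionMask(name, flags, 3.5),
                              descriptors=desc, vertex_ids=ids, name=name)

    def test_self_comparison_scores_one(self, sphere):
        e = self._entry(sphere, "a")
        S, labels, order = all_vs_all([e])
        assert S.shape == (1, 1) and S[0, 0] == 1.0

    def test_matrix_symmetric(self, sphere):
        ents = [self._entry(sphere, "a"), self._entry(sphere, "b", 500.0),
                self._entry(sphere, "c", 1000.0)]
        S, _, _ = all_vs_all(ents)
        assert np.abs(S - S.T).max() < 1e-12

    def test_planted_identical_pair_clusters_together(self, sphere):
        ents = [self._entry(sphere, "a", 0.0),
                self._entry(sphere, "a_twin", 0.0),
                self._entry(sphere, "unrelated", 500.0)]
        S, labels, _ = all_vs_all(ents, cluster_cut=0.5)
        assert S[0, 1] > 0.9          # identical interfaces
        assert S[0, 2] == 0.0
        assert labels[0] == labels[1] != labels[2]
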