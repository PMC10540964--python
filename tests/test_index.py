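import itertools

import numpy as np
import pytest

from lungcbir.index import (APConfig, RetrievalSphere, ValidationError,
                            ap_cluster, build_index, retrieve_pruned,
                            retrieve_sequential, top_k)


def neg_sq_euclidean(points):
    d = points[:, None, :] - points[None, :, :]
    return -(d ** 2).sum(axis=-1)


def two_blobs(rng, n_per=10, sep=10.0):
    a = rng.normal(0, 0.3, (n_per, 2))
    b = rng.normal(0, 0.3, (n_per, 2)) + sep
    return np.vstack([a, b])


def best_two_exemplar_partition(points):
    """Brute force: the pair of exemplars maximizing total similarity."""
    s = neg_sq_euclidean(points)
    n = len(points)
    best, best_val = None, -np.inf
    for i, j in itertools.combinations(range(n), 2):
        val = np.maximum(s[:, i], s[:, j]).sum()
        if val > best_val:
            best_val, best = val, (i, j)
    i, j = best
    return np.where(s[:, i] >= s[:, j], i, j)


class TestAPCluster:
    def test_single_point_is_its_own_exemplar(self):
        res = ap_cluster(np.array([[0.0]]))
        assert res.exemplars.tolist() == [0]

    def test_two_blobs_split_exactly(self, rng):
        pts = two_blobs(rng)
        res = ap_cluster(neg_sq_euclidean(pts), APConfig())
        assert len(res.exemplar_set) == 2
        ours = res.exemplars
        assert len(set(ours[:10])) == 1 and len(set(ours[10:])) == 1
        assert ours[0] != ours[10]
        oracle = best_two_exemplar_partition(pts)
        # identical partition (exemplar identities may differ from the
        # brute-force optimum only if similarity ties; compare groupings)
        assert (ours[:10] == ours[0]).all() == (oracle[:10] == oracle[0]).all()
        np.testing.assert_array_equal(ours == ours[0], oracle == oracle[0])

    def test_every_exemplar_self_assigned(self, rng):
        pts = rng.normal(0, 1, (25, 2))
        res = ap_cluster(neg_sq_euclidean(pts))
        for ex in res.exemplar_set:
            assert res.exemplars[ex] == ex

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check of the message-passing updates against
        scikit-learn's affinity propagation on the same similarities."""
        from sklearn.cluster import AffinityPropagation
        pts = np.vstack([rng.normal(0, 0.4, (8, 2)),
                         rng.normal(6, 0.4, (8, 2)),
                         rng.normal((0, 6), 0.4, (8, 2))])
        s = neg_sq_euclidean(pts)
        res = ap_cluster(s, APConfig(max_iter=500))
        ref = AffinityPropagation(affinity="precomputed", damping=0.5,
                                  max_iter=500, random_state=0).fit(s)
        ref_groups = {tuple(np.flatnonzero(ref.labels_ == l))
                      for l in set(ref.labels_)}
        our_groups = {tuple(np.flatnonzero(res.exemplars == e))
                      for e in res.exemplar_set}
        assert our_groups == ref_groups

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            ap_cluster(np.zeros((3, 4)))

    def test_bad_damping_rejected(self):
        with pytest.raises(ValidationError):
            APConfig(damping=0.3).validate()


class TestBuildIndex:
    def test_single_item(self):
        idx = build_index(1, lambda i, j: 0.0)
        assert len(idx.clusters) == 1
        assert idx.clusters[0].radius == 0.0

    def test_identical_points_one_cluster(self):
        idx = build_index(3, lambda i, j: 0.0)
        assert len(idx.clusters) == 1
        assert idx.clusters[0].radius == 0.0

    def test_radii_match_brute_force(self, rng):
        pts = rng.uniform(0, 1, (40, 2))

        def dist(i, j):
            return float(np.linalg.norm(pts[i] - pts[j]))

        idx = build_index(40, dist)
        all_members = np.concatenate([c.member_ids for c in idx.clusters])
        assert sorted(all_members.tolist()) == list(range(40))   # partition
        for c in idx.clusters:
            oracle = max(dist(c.center_id, int(m)) for m in c.member_ids)
            assert c.radius == pytest.approx(oracle)
            assert c.center_id in c.member_ids

    def test_random_center_mode_seeded(self, rng):
        pts = rng.uniform(0, 1, (20, 2))

        def dist(i, j):
            return float(np.linalg.norm(pts[i] - pts[j]))

        a = build_index(20, dist, center_mode="random")
        b = build_index(20, dist, center_mode="random")
        assert [c.center_id for c in a.clusters] == [c.center_id for c in b.clusters]

    def test_empty_database_rejected(self):
        with pytest.raises(ValidationError):
            build_index(0, lambda i, j: 0.0)


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(77)
    pts = rng.uniform(0, 1, (200, 2))

    def dist(i, j):
        return float(np.linalg.norm(pts[i] - pts[j]))

    idx = build_index(200, dist)
    return pts, idx


class TestRetrieval:

    def test_pruned_equals_sequential_for_metric_distance(self, instance):
        pts, idx = instance
        rng = np.random.default_rng(5)
        for _ in range(20):
            q = rng.uniform(0, 1, 2)
            r = float(rng.uniform(0.02, 0.4))

            def dq(i):
                return float(np.linalg.norm(pts[i] - q))

            sphere = RetrievalSphere(q, r)
            res_p, n_evals = retrieve_pruned(sphere, idx, dq)
            res_s = retrieve_sequential(sphere, 200, dq)
            np.testing.assert_array_equal(res_p, res_s)
            assert n_evals <= 200 + len(idx.clusters)

    def test_work_strictly_below_bound_when_pruning_happens(self, instance):
        pts, idx = instance
        q = np.array([0.0, 0.0])
        r = 0.05

        def dq(i):
            return float(np.linalg.norm(pts[i] - q))

        pruned_any = any(dq(c.center_id) > c.radius + r for c in idx.clusters)
        _, n_evals = retrieve_pruned(RetrievalSphere(q, r), idx, dq)
        assert pruned_any and n_evals < 200 + len(idx.clusters)

    def test_huge_radius_returns_everything(self, instance):
        pts, idx = instance

        def dq(i):
            return float(np.linalg.norm(pts[i]))

        res, _ = retrieve_pruned(RetrievalSphere(np.zeros(2), 10.0), idx, dq)
        assert res.tolist() == list(range(200))

    def test_zero_radius_returns_zero_distance_members(self, instance):
        pts, idx = instance
        q = pts[17]

        def dq(i):
            return float(np.linalg.norm(pts[i] - q))

        res, _ = retrieve_pruned(RetrievalSphere(q, 0.0), idx, dq)
        assert 17 in res.tolist()
        assert all(dq(i) == 0.0 for i in res)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValidationError):
            RetrievalSphere(None, -0.1)


class TestTopK:
    def test_matches_brute_force_sort(self, rng):
        pts = rng.uniform(0, 1, (30, 2))
        q = rng.uniform(0, 1, 2)
        d = np.linalg.norm(pts - q, axis=1)
        got = top_k(7, 30, lambda i: float(d[i]))
        oracle = sorted(range(30), key=lambda i: (d[i], i))[:7]
        assert [i for i, _ in got] == oracle

    def test_query_in_database_ranks_first(self, rng):
        pts = rng.uniform(0, 1, (10, 2))
        d = np.linalg.norm(pts - pts[4], axis=1)
        got = top_k(3, 10, lambda i: float(d[i]))
        assert got[0][0] == 4 and got[0][1] == 0.0

    def test_k_equals_n_full_sort(self, rng):
        d = rng.uniform(0, 1, 12)
        got = top_k(12, 12, lambda i: float(d[i]))
        assert [i for i, _ in got] == np.argsort(d, kind="stable").tolist()

    def test_k_beyond_n_warns_and_returns_all(self, rng, caplog):
        import logging
        d = rng.uniform(0, 1, 5)
        with caplog.at_level(logging.WARNING):
            got = top_k(9, 5, lambda i: float(d[i]))
        assert len(got) == 5 and "exceeds" in caplog.text
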