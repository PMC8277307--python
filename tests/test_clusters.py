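"""K-means topic extraction, silhouette k-selection and cluster filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import silhouette_brute
from vaxtopics.clusters import (
    ClusterAssignment,
    filter_prominent,
    is_handle_cluster,
    kmeans_fit,
    mean_silhouette,
    prominence_threshold,
    select_k,
    top_terms,
)
from vaxtopics.features import TweetVectorizer, build_vocabulary, vectorize
from vaxtopics.synthetic import CorpusSpec, generate_corpus, generate_geometry


class TestKMeansFit:
    def test_k1_centroid_is_column_mean(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        assign = kmeans_fit(X, 1, seed=0)
        assert np.allclose(assign.centroids[0], X.mean(axis=0))
        assert np.all(assign.labels == 0)

    def test_two_far_blobs_recover_planted_partition(self):
        g = generate_geometry(2, 20.0, 0.5, 30, 4, seed=1)
        assign = kmeans_fit(g.points, 2, seed=0)
        same = (assign.labels == assign.labels[0])[g.assignment == 0]
        assert np.all(same) or not np.any(same[1:])
        # every planted cluster maps to exactly one fitted cluster
        for c in (0, 1):
            assert len(np.unique(assign.labels[g.assignment == c])) == 1

    def test_k_equal_rows_gives_zero_inertia(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        assign = kmeans_fit(X, 6, seed=0)
        assert assign.inertia == pytest.approx(0.0)

    def test_k_beyond_rows_rejected(self):
        with pytest.raises(ValueError, match="k="):
            kmeans_fit(np.zeros((3, 2)), 4)

    def test_row_normalization_makes_length_irrelevant(self):
        # two directions, each at two very different magnitudes: raw
        # counts split by magnitude, normalized rows split by direction
        X = np.array(
            [[1.0, 0.0], [30.0, 0.0], [0.0, 1.0], [0.0, 30.0]]
        )
        raw = kmeans_fit(X, 2, seed=0)
        assert raw.labels[3] != raw.labels[0]  # raw counts: magnitude dominates
        norm = kmeans_fit(X, 2, seed=0, normalize_rows=True)
        assert norm.labels[0] == norm.labels[1]
        assert norm.labels[2] == norm.labels[3]
        assert norm.labels[0] != norm.labels[2]


class TestMeanSilhouette:
    def test_two_tight_far_blobs_score_near_one(self):
        g = generate_geometry(2, 50.0, 0.1, 25, 3, seed=0)
        assert mean_silhouette(g.points, g.assignment) > 0.95

    def test_random_split_of_one_blob_scores_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        labels = rng.integers(0, 2, size=100)
        assert abs(mean_silhouette(X, labels)) < 0.1

    def test_four_point_instance_matches_hand_enumeration(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        assert mean_silhouette(X, labels) == pytest.approx(
            silhouette_brute(X, labels), abs=1e-9
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            mean_silhouette(np.zeros((5, 2)), [0] * 5)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        X = rng.normal(size=(n, 2))
        labels = rng.integers(0, 3, size=n)
        if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= n:
            labels[: len(np.unique(labels)) + 1] = np.arange(len(np.unique(labels)) + 1) % 2
        if len(np.unique(labels)) < 2:
            return
        s = mean_silhouette(X, labels)
        assert -1.0 <= s <= 1.0
        assert s == pytest.approx(silhouette_brute(X, labels), abs=1e-9)


class TestSelectK:
    def test_three_planted_blobs_selected(self):
        g = generate_geometry(3, 12.0, 1.0, 30, 5, seed=2)
        k_best, curve = select_k(g.points, range(2, 7), seed=0)
        assert k_best == 3
        assert curve.k_values == (2, 3, 4, 5, 6)
        assert all(-1 <= s <= 1 for s in curve.scores)

    def test_single_k_range_returns_it(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        k_best, curve = select_k(X, [4], seed=0)
        assert k_best == 4 and curve.k_values == (4,)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_k(np.zeros((10, 2)), [])

    def test_tie_prefers_smallest_k(self):
        from vaxtopics.clusters import SilhouetteCurve

        # documented tie-break exercised through the selection loop:
        # perfectly symmetric four-point square ties several k
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        k_best, curve = select_k(X, [2, 3], seed=0)
        assert k_best == 2  # k=2 wins; at a tie the smaller k is kept
        assert isinstance(curve, SilhouetteCurve)


class TestProminence:
    def test_study_sized_threshold(self):
        assert prominence_threshold(9440, 0.05) == 472

    def test_zero_total(self):
        assert prominence_threshold(0) == 0

    def test_ceiling_behavior(self):
        assert prominence_threshold(20, 0.05) == 1
        assert prominence_threshold(21, 0.05) == 2

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            prominence_threshold(10, 0.0)

    def _assignment(self, sizes):
        labels = np.concatenate([[i] * s for i, s in enumerate(sizes)])
        return ClusterAssignment(
            k=len(sizes), labels=labels, centroids=np.zeros((len(sizes), 2)), inertia=0.0
        )

    def test_four_prominent_clusters_at_threshold_472(self):
        sizes = [2450, 1732, 1256, 984] + [300, 200, 100, 50]
        pset = filter_prominent(self._assignment(sizes), 472)
        assert len(pset.prominent) == 4
        assert set(pset.prominent) == {0, 1, 2, 3}

    def test_threshold_zero_makes_all_prominent(self):
        pset = filter_prominent(self._assignment([5, 5, 5]), 0)
        assert pset.prominent == (0, 1, 2) and pset.rest == ()

    def test_all_below_threshold_gives_empty_prominent(self):
        pset = filter_prominent(self._assignment([5, 5]), 10)
        assert pset.prominent == () and pset.rest == (0, 1)

    def test_partition_prominent_rest_excluded_covers_all(self):
        sizes = [50, 40, 30, 20, 10]
        pset = filter_prominent(self._assignment(sizes), 25, excluded=[1])
        all_ids = set(pset.prominent) | set(pset.rest) | set(pset.excluded_handle_clusters)
        assert all_ids == {0, 1, 2, 3, 4}
        assert not set(pset.prominent) & set(pset.excluded_handle_clusters)
        assert 1 in pset.excluded_handle_clusters


class TestTopTerms:
    def _single_cluster(self, n_rows):
        return ClusterAssignment(
            k=1, labels=np.zeros(n_rows, dtype=int), centroids=np.zeros((1, 1)), inertia=0.0
        )

    def test_frequency_then_lexicographic_order(self):
        tokens = [["#a", "#a", "@b"]] * 3
        vocab = build_vocabulary([["#a", "@b"]])  # unigram-level vocabulary
        X = vectorize(tokens, vocab)
        top = top_terms(X, self._single_cluster(3), 0, vocab, n=50, kinds=("hashtag", "mention"))
        assert top == ["#a", "@b"]

    def test_n_larger_than_vocabulary_returns_full_ranking(self):
        vocab = build_vocabulary([["x", "y"]])
        X = vectorize([["x", "y", "y"]], vocab)
        top = top_terms(X, self._single_cluster(1), 0, vocab, n=1000)
        assert top == ["y", "x", "x y"]

    def test_unknown_cluster_rejected(self):
        vocab = build_vocabulary([["x"]])
        X = vectorize([["x"]], vocab)
        with pytest.raises(ValueError, match="cluster"):
            top_terms(X, self._single_cluster(1), 3, vocab)


class TestHandleClusters:
    def test_all_mentions_flagged(self):
        vocab = build_vocabulary([[f"@u{i}" for i in range(10)]])
        top = [f"@u{i}" for i in range(10)]
        assert is_handle_cluster(top, vocab)

    def test_one_hashtag_breaks_the_flag(self):
        vocab = build_vocabulary([["@a", "@b", "#c"]])
        assert not is_handle_cluster(["@a", "#c", "@b"], vocab)

    def test_small_vocabulary_uses_all_available(self):
        vocab = build_vocabulary([["@a", "@b"]])
        assert is_handle_cluster(["@a", "@b"], vocab)

    def test_synthetic_handle_cluster_detected_end_to_end(self):
        spec = CorpusSpec(n_per_class=(30, 30, 0), handle_cluster_sizes=(25,), seed=6)
        tweets = generate_corpus(spec)
        vec = TweetVectorizer().fit([t.text for t in tweets])
        X = vec.transform([t.text for t in tweets])
        handle_rows = np.array([t.true_topic is None for t in tweets])
        labels = handle_rows.astype(int)
        assign = ClusterAssignment(
            k=2, labels=labels, centroids=np.zeros((2, X.shape[1])), inertia=0.0
        )
        top = top_terms(
            X, assign, 1, vec.vocabulary_, n=50, kinds=("unigram", "hashtag", "mention")
        )
        assert is_handle_cluster(top, vec.vocabulary_)
        top0 = top_terms(
            X, assign, 0, vec.vocabulary_, n=50, kinds=("unigram", "hashtag", "mention")
        )
        assert not is_handle_cluster(top0, vec.vocabulary_)
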