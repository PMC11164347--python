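import numpy as np
import pytest

from conformal_ec.ontology import AnnotationSet, parse_ec
from conformal_ec.predictor import (
    ClusterTable,
    EmbeddingTable,
    NearestClusterScorer,
    SkipTriplet,
    cluster_embeddings,
    distances_to_scores,
    max_separation_set,
    positive_control_stats,
    query_distances,
    sample_triplet,
    sigma_threshold_set,
    top1_set,
)

E = parse_ec
LABELS = [E("1.1.1.1"), E("1.1.1.2"), E("2.3.4.5"), E("3.1.1.1")]


class TestClusterEmbeddings:
    def test_centroid_is_member_mean(self):
        emb = EmbeddingTable(["A", "B"], [[0.0, 0.0], [2.0, 2.0]])
        ann = AnnotationSet({"A": {LABELS[0]}, "B": {LABELS[0]}})
        ct = cluster_embeddings(emb, ann)
        assert np.allclose(ct.centroids[0], [1.0, 1.0])
        assert ct.member_count[0] == 2

    def test_singleton_cluster_equals_member(self):
        emb = EmbeddingTable(["A"], [[3.0, -1.0]])
        ann = AnnotationSet({"A": {LABELS[0]}})
        ct = cluster_embeddings(emb, ann)
        assert np.allclose(ct.centroids[0], [3.0, -1.0])

    def test_promiscuous_protein_joins_every_cluster(self):
        rng = np.random.default_rng(1)
        vectors = rng.normal(size=(6, 3))
        emb = EmbeddingTable([f"P{i}" for i in range(6)], vectors)
        labels_of = {
            "P0": {LABELS[0], LABELS[1]},
            "P1": {LABELS[0]},
            "P2": {LABELS[1]},
            "P3": {LABELS[2]},
            "P4": {LABELS[2], LABELS[0]},
            "P5": {LABELS[1]},
        }
        ann = AnnotationSet(labels_of)
        ct = cluster_embeddings(emb, ann)
        # explicit double-loop oracle
        for j, ec in enumerate(ct.labels):
            members = [
                vectors[i]
                for i, pid in enumerate(ann.proteins)
                if ec in labels_of[pid]
            ]
            assert np.allclose(
                ct.centroids[j], np.mean(members, axis=0), atol=1e-9
            )

    def test_missing_embedding_rejected(self):
        emb = EmbeddingTable(["A"], [[0.0]])
        ann = AnnotationSet({"A": {LABELS[0]}, "B": {LABELS[1]}})
        with pytest.raises(ValueError, match="without embeddings"):
            cluster_embeddings(emb, ann)


class TestQueryDistances:
    def test_zero_at_own_centroid_and_345(self):
        ct = ClusterTable(LABELS[:2], [[0.0, 0.0], [3.0, 4.0]], [1, 1])
        d = query_distances(np.array([0.0, 0.0]), ct)
        assert d[0] == 0.0
        assert d[1] == pytest.approx(5.0)

    def test_dimension_mismatch(self):
        ct = ClusterTable(LABELS[:1], [[0.0, 0.0]], [1])
        with pytest.raises(ValueError):
            query_distances(np.zeros(3), ct)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(2)
        cents = rng.normal(size=(4, 5))
        q = rng.normal(size=5)
        ct = ClusterTable(LABELS, cents, [1] * 4)
        d = query_distances(q, ct)
        perm = rng.permutation(4)
        ct2 = ClusterTable(
            [LABELS[i] for i in perm], cents[perm], [1] * 4
        )
        assert np.allclose(query_distances(q, ct2), d[perm])


class TestDistancesToScores:
    def test_zero_distance_maps_to_one(self):
        assert distances_to_scores(np.array([0.0]), tau=0.5)[0] == 1.0

    def test_strictly_decreasing(self):
        s = distances_to_scores(np.array([0.1, 0.2]), tau=1.0)
        assert s[0] > s[1]

    def test_rank_reversal_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.random(8) * 5
            s = distances_to_scores(d, tau=0.7)
            assert np.array_equal(np.argsort(d), np.argsort(-s))


class TestCutoffBaselines:
    def test_max_separation_cuts_at_largest_gap(self):
        d = np.array([0.1, 0.15, 0.6, 0.62])
        assert max_separation_set(d, LABELS) == {LABELS[0], LABELS[1]}

    def test_two_labels_takes_closest(self):
        assert max_separation_set(np.array([0.1, 0.9]), LABELS[:2]) == {
            LABELS[0]
        }

    def test_all_equal_falls_back_to_top1(self):
        assert max_separation_set(np.array([0.4, 0.4, 0.4]), LABELS[:3]) == {
            LABELS[0]
        }

    def test_top1_min_and_tie_break(self):
        assert top1_set(np.array([0.3, 0.2]), LABELS[:2]) == {LABELS[1]}
        assert top1_set(np.array([0.2, 0.2]), LABELS[:2]) == {LABELS[0]}

    def test_top1_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = rng.random(len(LABELS))
            best = min(range(len(d)), key=lambda i: d[i])
            assert top1_set(d, LABELS) == {LABELS[best]}

    def test_monotone_transform_invariance(self):
        # top-1 depends only on the distance ranking; max-separation also
        # depends on gap magnitudes, so it is invariant under increasing
        # affine maps (which rescale all gaps equally) but not under
        # arbitrary monotone warps
        rng = np.random.default_rng(5)
        d = rng.random(6) * 2
        labels = [E(f"1.1.1.{i+1}") for i in range(6)]
        for f in (lambda x: 3 * x + 1, np.exp, np.sqrt):
            assert top1_set(f(d), labels) == top1_set(d, labels)
        for a, b in ((2.0, 0.5), (10.0, 0.0), (0.1, 3.0)):
            assert max_separation_set(a * d + b, labels) == max_separation_set(
                d, labels
            )

    def test_sigma_threshold_strict_cutoff(self):
        d = np.array([0.2, 0.49, 0.7])
        assert sigma_threshold_set(d, LABELS[:3], mu=0.3, sigma=0.1) == {
            LABELS[0],
            LABELS[1],
        }

    def test_sigma_zero_uses_mu(self):
        d = np.array([0.1, 0.3, 0.5])
        assert sigma_threshold_set(d, LABELS[:3], mu=0.3, sigma=0.0) == {
            LABELS[0]
        }

    def test_cutoff_below_everything_is_empty(self):
        d = np.array([0.5, 0.6])
        assert sigma_threshold_set(d, LABELS[:2], mu=0.1, sigma=0.05) == set()


class TestPositiveControlStats:
    def test_constant_distances(self):
        emb = EmbeddingTable(["A", "B"], [[0.0], [2.0]])
        ann = AnnotationSet({"A": {LABELS[0]}, "B": {LABELS[1]}})
        # singleton clusters: both true distances are 0
        mu, sigma = positive_control_stats(emb, ann, cluster_embeddings(emb, ann))
        assert (mu, sigma) == (0.0, 0.0)

    def test_population_sd(self):
        ct = ClusterTable(LABELS[:2], [[1.0], [1.0]], [1, 1])
        emb = EmbeddingTable(["A", "B"], [[1.0], [3.0]])
        ann = AnnotationSet({"A": {LABELS[0]}, "B": {LABELS[1]}})
        mu, sigma = positive_control_stats(emb, ann, ct)
        assert mu == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)  # population (n) denominator

    def test_matches_two_pass_oracle(self, small_dataset):
        cfg, ann, _, emb = small_dataset
        ct = cluster_embeddings(emb, ann)
        mu, sigma = positive_control_stats(emb, ann, ct)
        dists = []
        col = {ec: j for j, ec in enumerate(ct.labels)}
        for i, pid in enumerate(ann.proteins):
            for ec in ann[pid]:
                dists.append(
                    np.linalg.norm(emb.vectors[i] - ct.centroids[col[ec]])
                )
        assert mu == pytest.approx(np.mean(dists), abs=1e-9)
        assert sigma == pytest.approx(np.std(dists), abs=1e-9)


class TestSampleTriplet:
    def _annotations(self):
        return AnnotationSet(
            {
                "anchor": {LABELS[0], LABELS[1]},
                "pos0": {LABELS[0]},
                "pos1": {LABELS[0], LABELS[2]},
                "posB": {LABELS[1]},
                "neg0": {LABELS[2]},
                "neg1": {LABELS[3]},
                "shares": {LABELS[1], LABELS[2]},  # ineligible negative
            }
        )

    def test_positive_shares_selected_ec_negative_shares_none(self):
        ann = self._annotations()
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, p, n = sample_triplet("anchor", ann, rng)
            assert a == "anchor"
            assert ann[p] & ann["anchor"]
            assert not (ann[n] & ann["anchor"])
            assert n in {"neg0", "neg1"}

    def test_skip_when_no_negative(self):
        ann = AnnotationSet(
            {"anchor": {LABELS[0]}, "pos": {LABELS[0]}}
        )
        with pytest.raises(SkipTriplet):
            sample_triplet("anchor", ann, np.random.default_rng(0))

    def test_deterministic_under_seed(self):
        ann = self._annotations()
        t1 = [sample_triplet("anchor", ann, np.random.default_rng(7))
              for _ in range(5)]
        t2 = [sample_triplet("anchor", ann, np.random.default_rng(7))
              for _ in range(5)]
        assert t1 == t2

    def test_positive_selection_uniform(self):
        ann = AnnotationSet(
            {
                "anchor": {LABELS[0]},
                "p1": {LABELS[0]},
                "p2": {LABELS[0]},
                "p3": {LABELS[0]},
                "n": {LABELS[2]},
            }
        )
        rng = np.random.default_rng(123)
        counts = {"p1": 0, "p2": 0, "p3": 0}
        n_draws = 10_000
        for _ in range(n_draws):
            _, p, _ = sample_triplet("anchor", ann, rng)
            counts[p] += 1
        expected = n_draws / 3
        sd = np.sqrt(n_draws * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - expected) <= 3 * sd


class TestNearestClusterScorer:
    def test_fit_transform_scores_in_unit_interval(self, small_dataset):
        cfg, ann, _, emb = small_dataset
        scorer = NearestClusterScorer().fit(emb, ann)
        sm = scorer.transform(emb)
        assert sm.scores.shape == (len(emb), len(scorer.labels_))
        assert (sm.scores > 0).all() and (sm.scores <= 1).all()

    def test_score_threshold_equals_distance_threshold(self, small_dataset):
        # thresholding scores at lam is thresholding distances at -tau ln lam
        cfg, ann, _, emb = small_dataset
        scorer = NearestClusterScorer().fit(emb, ann)
        sm = scorer.transform(emb)
        d = scorer.distances(emb)
        rng = np.random.default_rng(8)
        for lam in rng.uniform(0.05, 0.95, size=5):
            by_score = sm.scores >= lam
            by_dist = d <= -scorer.tau_ * np.log(lam)
            assert np.array_equal(by_score, by_dist)

    def test_baseline_strategies_produce_nonempty_sets(self, small_dataset):
        cfg, ann, _, emb = small_dataset
        scorer = NearestClusterScorer().fit(emb, ann)
        for strategy in ("top1", "max-separation"):
            sets = scorer.predict_baseline(emb, strategy)
            assert len(sets) == len(emb)
            assert all(len(s) >= 1 for s in sets)
        sets = scorer.predict_baseline(emb, "sigma-threshold")
        assert len(sets) == len(emb)

    def test_cosine_metric_supported(self, small_dataset):
        cfg, ann, _, emb = small_dataset
        scorer = NearestClusterScorer(metric="cosine").fit(emb, ann)
        assert scorer.distances(emb).min() >= 0
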