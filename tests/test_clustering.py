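"""Scaling, ARI, K-means ensembles, K selection, representative assignment,
CV reproducibility and replication assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radsubtypes.clustering import (
    ClusterRunSet, FeatureScaler, ImagingSubtyper, SubtypeModel,
    adjusted_rand_index, assign_new, average_pairwise_ari,
    centroids_from_labels, cv_reproducibility, feature_association,
    representative_assignment, run_kmeans_ensemble, select_k, silhouette_mean,
)


def pair_counting_ari(a, b):
    """Brute-force oracle: Hubert–Arabie ARI from item-pair agreement counts."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa and not sb:
            n10 += 1
        elif not sa and sb:
            n01 += 1
        else:
            n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def all_partitions(n):
    """Every set partition of n items as a label vector (restricted growth)."""
    def rec(prefix, k):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))
    yield from rec([0], 1)


class TestScaling:
    def test_min_max_mapping(self):
        frame = pd.DataFrame({"f": [2.0, 4.0, 6.0]})
        scaled = FeatureScaler().fit_transform(frame)
        assert list(scaled["f"]) == [0.0, 0.5, 1.0]

    def test_constant_column_flagged_and_zeroed(self):
        frame = pd.DataFrame({"f": [3.0, 3.0, 3.0], "g": [0.0, 1.0, 2.0]})
        scaler = FeatureScaler().fit(frame)
        assert scaler.constant_[0] and not scaler.constant_[1]
        assert (scaler.transform(frame)["f"] == 0).all()

    def test_replication_values_not_clipped(self):
        scaler = FeatureScaler().fit(pd.DataFrame({"f": [2.0, 4.0, 6.0]}))
        out = scaler.transform(pd.DataFrame({"f": [8.0]}))
        assert out["f"].iloc[0] == pytest.approx(1.5)

    def test_unknown_feature_errors(self):
        scaler = FeatureScaler().fit(pd.DataFrame({"f": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="mismatch"):
            scaler.transform(pd.DataFrame({"g": [1.0]}))

    def test_idempotent_unit_interval(self, small_table):
        scaled = FeatureScaler().fit_transform(small_table.frame)
        assert scaled.to_numpy().min() >= 0.0
        assert scaled.to_numpy().max() <= 1.0


class TestARI:
    def test_label_permutation_gives_one(self):
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_crossed_partition(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_self_agreement(self):
        labels = [0, 1, 1, 2, 0]
        assert adjusted_rand_index(labels, labels) == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            adjusted_rand_index([1, 2], [1, 2, 3])

    def test_exhaustive_pair_counting_oracle(self):
        """ARI equals the brute-force pair-counting oracle for every pair of
        partitions of 5 items."""
        parts = list(all_partitions(5))
        for a in parts:
            for b in parts:
                assert adjusted_rand_index(a, b) == pytest.approx(
                    pair_counting_ari(a, b), abs=1e-12)


class TestEnsemble:
    def test_planted_partition_dominates_ensemble(self, highdim_blobs):
        """Most runs recover the planted partition; single-start random-init
        Lloyd caps run-pair agreement below 1 (local optima), so the ensemble
        is judged by its average ARI and its modal partition class."""
        X, truth = highdim_blobs
        runs = run_kmeans_ensemble(X, 3, n_runs=40, seed=0)
        assert average_pairwise_ari(runs) >= 0.8
        modal = runs.partition_classes()[0][0]
        assert adjusted_rand_index(modal, truth) == 1.0

    def test_single_run(self, blobs):
        X, _ = blobs
        runs = run_kmeans_ensemble(X, 3, n_runs=1, seed=0)
        assert runs.n_runs == 1

    def test_deterministic_under_master_seed(self, blobs):
        X, _ = blobs
        a = run_kmeans_ensemble(X, 4, n_runs=10, seed=5)
        b = run_kmeans_ensemble(X, 4, n_runs=10, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            run_kmeans_ensemble(np.zeros((3, 2)), 4, n_runs=1)


class TestSelectK:
    def test_planted_three_clusters_chosen(self, highdim_blobs):
        X, _ = highdim_blobs
        report = select_k(X, k_range=range(2, 7), n_runs=40, seed=0)
        assert report.chosen_k == 3
        assert report.average_ari[3] >= 0.8
        assert set(report.average_ari) == {2, 3, 4, 5, 6}

    def test_single_blob_less_stable_than_planted(self, highdim_blobs):
        rng = np.random.default_rng(1)
        single = rng.normal(size=(90, 10))
        rep_single = select_k(single, k_range=[2], n_runs=40, seed=0)
        X, _ = highdim_blobs
        rep_planted = select_k(X, k_range=[3], n_runs=40, seed=0)
        assert rep_single.average_ari[2] < rep_planted.average_ari[3] - 0.2


class TestRepresentative:
    def test_all_runs_identical(self, blobs):
        X, truth = blobs
        runs = run_kmeans_ensemble(X, 3, n_runs=10, seed=0)
        rep = representative_assignment(X, runs)
        assert adjusted_rand_index(rep, truth) == 1.0

    def test_silhouette_beats_frequency(self):
        """60%/40% split between two partition classes: the winner is the one
        with higher silhouette, not higher frequency."""
        X = np.array([[0.0, 0], [0, 0.1], [10, 10], [10, 10.1]])
        good = np.array([0, 0, 1, 1])       # true pairing, silhouette ~ 1
        bad = np.array([0, 1, 0, 1])        # crossed pairing, negative silhouette
        labels = np.vstack([bad] * 6 + [good] * 4)
        runs = ClusterRunSet(k=2, labels=labels, seeds=np.arange(10))
        rep = representative_assignment(X, runs)
        assert adjusted_rand_index(rep, good) == 1.0

    def test_fallback_to_most_frequent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 2))
        # 7 distinct partitions (different split points), max frequency 3/20 = 15%
        splits = [np.array([0] * s + [1] * (8 - s)) for s in range(1, 8)]
        labels = np.vstack([splits[0]] * 2
                           + [lab for lab in splits[1:] for _ in range(3)])
        runs = ClusterRunSet(k=2, labels=labels, seeds=np.arange(20))
        with pytest.warns(UserWarning, match="threshold"):
            rep = representative_assignment(X, runs, frequency_threshold=0.2)
        classes = runs.partition_classes()
        assert adjusted_rand_index(rep, classes[0][0]) == 1.0
        assert classes[0][1] == max(c for _, c in classes)


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        X = np.array([[0.0, 0], [0, 0.1], [10, 10], [10, 10.1]])
        assert silhouette_mean(X, [0, 0, 1, 1]) > 0.9

    def test_unstructured_data_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 2))
        labels = rng.integers(0, 2, size=400)
        assert abs(silhouette_mean(X, labels)) < 0.05

    def test_consistent_relabeling_invariance(self, blobs):
        X, truth = blobs
        swapped = np.array([{0: 2, 1: 0, 2: 1}[t] for t in truth])
        assert silhouette_mean(X, truth) == pytest.approx(silhouette_mean(X, swapped))

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            silhouette_mean(np.zeros((4, 2)), [0, 0, 0, 0])


class TestCVReproducibility:
    def test_planted_partition_fully_reproducible(self, blobs):
        X, _ = blobs
        assert cv_reproducibility(X, 3, folds=10, seed=0, n_runs=20) == 100.0

    def test_unstructured_below_planted(self):
        # K-means quantization of structureless data is partly stable, so
        # reproducibility is not near chance, but averaged over draws it
        # stays well below the planted-case 100%
        pcts = []
        for seed in (3, 5, 9):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 5))
            pcts.append(cv_reproducibility(X, 3, folds=10, seed=0, n_runs=20))
        assert np.mean(pcts) < 90.0
        assert min(pcts) < 85.0

    def test_single_fold_invalid(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError, match="folds"):
            cv_reproducibility(X, 3, folds=1)


class TestAssignNew:
    def _model(self, blobs):
        X, truth = blobs
        frame = pd.DataFrame(X, columns=["a", "b"])
        scaler = FeatureScaler().fit(frame)
        scaled = scaler.transform(frame)
        centroids = centroids_from_labels(scaled, truth, 3)
        return SubtypeModel(k=3, centroids=centroids, scaler=scaler,
                            feature_names=["a", "b"]), frame, truth

    def test_centroid_maps_to_own_cluster(self, blobs):
        model, frame, truth = self._model(blobs)
        raw_centroids = model.centroids * (model.scaler.max_ - model.scaler.min_) + model.scaler.min_
        preds = assign_new(model, pd.DataFrame(raw_centroids, columns=["a", "b"]))
        assert list(preds) == [0, 1, 2]

    def test_held_out_subjects_recovered(self, blobs):
        model, frame, truth = self._model(blobs)
        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        new = np.vstack([rng.normal(c, 0.4, size=(10, 2)) for c in centers])
        preds = assign_new(model, pd.DataFrame(new, columns=["a", "b"]))
        assert (preds == np.repeat([0, 1, 2], 10)).mean() >= 0.9

    def test_equidistant_tie_goes_to_lowest_index(self):
        frame = pd.DataFrame({"a": [0.0, 2.0]})
        scaler = FeatureScaler().fit(frame)
        model = SubtypeModel(k=2, centroids=np.array([[0.0], [1.0]]),
                             scaler=scaler, feature_names=["a"])
        pred = assign_new(model, pd.DataFrame({"a": [1.0]}))  # scales to 0.5
        assert pred[0] == 0

    def test_missing_feature_errors(self, blobs):
        model, _, _ = self._model(blobs)
        with pytest.raises(ValueError, match="missing"):
            assign_new(model, pd.DataFrame({"a": [0.0]}))


class TestFeatureAssociation:
    def test_identical_groups_give_zero_h(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=60)
        frame = pd.DataFrame({"f": np.concatenate([vals[:30], vals[:30]])})
        labels = np.repeat([0, 1], 30)
        out = feature_association(frame, labels)
        assert out.loc["f", "H"] == pytest.approx(0.0, abs=1e-9)

    def test_separated_groups_significant_after_bonferroni(self):
        rng = np.random.default_rng(6)
        n_features = 278
        frame = pd.DataFrame(rng.normal(size=(150, n_features)),
                             columns=[f"f{i}" for i in range(n_features)])
        labels = np.repeat([0, 1, 2], 50)
        frame["f0"] = np.concatenate([rng.normal(m, 1, 50) for m in (0, 5, 10)])
        out = feature_association(frame, labels)
        assert out.loc["f0", "significant"]
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_empty_group_errors(self):
        frame = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            feature_association(frame, [0, 0])


class TestSubtypeModelRoundTrip:
    def test_json_round_trip_preserves_assignments(self, blobs):
        X, truth = blobs
        frame = pd.DataFrame(X, columns=["a", "b"])
        sub = ImagingSubtyper(k=3, n_runs=10, random_state=0).fit(frame)
        payload = sub.model_.to_json_obj()
        import json
        restored = SubtypeModel.from_json_obj(json.loads(json.dumps(payload)))
        np.testing.assert_array_equal(assign_new(restored, frame),
                                      assign_new(sub.model_, frame))
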