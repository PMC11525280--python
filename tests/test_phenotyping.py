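"""Clustering, SOM contracts, forest importance, dominance, subtyping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from pdmotion.errors import ValidationError
from pdmotion.phenotyping import (
    ClusterAssignment,
    SOMModel,
    classify_cohort,
    compare_partitions,
    dominance,
    eggers_classify,
    rf_importance,
    som_fit,
    train_som,
    tsne_kmeans,
    ward_cut,
)


def _blobs(rng, centers, n_per, sd=0.5):
    centers = np.asarray(centers, float)
    labels = np.repeat(np.arange(len(centers)), n_per)
    X = centers[labels] + sd * rng.standard_normal((labels.size, centers.shape[1]))
    return X, labels


class TestTsneKmeans:
    def test_separated_blobs_recovered_exactly(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, truth = _blobs(rng, [[0, 0], [10, 0], [0, 10]], 20)
            assign, _ = tsne_kmeans(X, k=3, seed=seed)
            assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_k_of_one_labels_everything_together(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        assign, _ = tsne_kmeans(X, k=1, perplexity=10, seed=0)
        assert np.all(assign.labels == 1)

    def test_small_cohort_warns_but_runs(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4))
        with pytest.warns(UserWarning, match="perplexity"):
            assign, emb = tsne_kmeans(X, k=3, perplexity=30, seed=0)
        assert emb.shape == (50, 2)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValidationError):
            tsne_kmeans(np.zeros((5, 2)), k=6)


class TestSom:
    def test_zero_epochs_with_data_as_weights_gives_zero_qe(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((9, 4))
        model = som_fit(X, 3, 3, epochs=0, initial_neighborhood=2.0, init_weights=X)
        assert model.qe == pytest.approx(0.0, abs=1e-12)

    def test_single_neuron_converges_to_centroid(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 3)) + [2.0, -1.0, 0.5]
        model = som_fit(X, 1, 1, epochs=200, initial_neighborhood=1.0, seed=5)
        ref = float(np.linalg.norm(X - X.mean(axis=0), axis=1).mean())
        assert model.qe <= ref * 1.05

    def test_search_returns_lowest_qe_configuration(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        best = train_som(X, grid_sizes=[(2, 2), (3, 3)], epochs_list=[5, 20],
                         neighborhood_list=[1.5], restarts=3, seed=9)
        # retrain every config: none may beat the returned model
        root = np.random.SeedSequence(9)
        for rows, cols in [(2, 2), (3, 3)]:
            for epochs in [5, 20]:
                for child in np.random.SeedSequence(9).spawn(3):
                    m = som_fit(X, rows, cols, epochs, 1.5, seed=child)
                    assert best.qe <= m.qe + 1e-12

    def test_qe_tends_to_decrease_with_training(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 4))
        qes = []
        for seed in range(10):
            short = som_fit(X, 4, 4, epochs=2, initial_neighborhood=2.0, seed=seed)
            long = som_fit(X, 4, 4, epochs=40, initial_neighborhood=2.0, seed=seed)
            qes.append(long.qe < short.qe)
        assert sum(qes) >= 8


class TestWardCut:
    def _som_with_weights(self, weights):
        return SOMModel(rows=len(weights), cols=1, weights=np.asarray(weights, float))

    def test_blob_weights_recovered_at_matching_k(self):
        rng = np.random.default_rng(6)
        W, w_labels = _blobs(rng, [[0, 0], [20, 0], [0, 20]], 4, sd=0.3)
        som = self._som_with_weights(W)
        X = W + 0.01 * rng.standard_normal(W.shape)
        cuts = ward_cut(som, X, k_list=(3,))
        assert adjusted_rand_score(w_labels, cuts[3].labels) == 1.0

    def test_cuts_are_nested_across_k(self):
        rng = np.random.default_rng(7)
        som = self._som_with_weights(rng.standard_normal((12, 3)))
        X = rng.standard_normal((30, 3))
        cuts = ward_cut(som, X, k_list=(2, 3, 4))
        for k_fine, k_coarse in ((3, 2), (4, 3)):
            fine, coarse = cuts[k_fine].labels, cuts[k_coarse].labels
            # every fine cluster sits inside exactly one coarse cluster
            for c in np.unique(fine):
                assert np.unique(coarse[fine == c]).size == 1

    def test_duplicate_neurons_merge_at_height_zero(self):
        from scipy.cluster.hierarchy import linkage

        W = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        Z = linkage(W, method="ward")
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_k_above_neuron_count_rejected(self):
        som = self._som_with_weights(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            ward_cut(som, np.zeros((5, 2)), k_list=(4,))


class TestRfImportance:
    def test_planted_signal_ranked_first_in_every_run(self):
        rng = np.random.default_rng(8)
        n = 60
        labels = np.repeat([1, 2], n // 2)
        X = rng.standard_normal((n, 8))
        X[:, 3] = labels + 0.05 * rng.standard_normal(n)
        for seed in range(10):
            ranked = rf_importance(X, labels, n_seeds=1, n_trees=100, seed=seed)
            assert ranked["feature"].iloc[0] == "f3"

    def test_uninformative_features_have_near_zero_importance(self):
        rng = np.random.default_rng(9)
        n = 60
        labels = np.repeat([1, 2], n // 2)
        X = rng.standard_normal((n, 6))
        ranked = rf_importance(X, labels, n_seeds=5, n_trees=100, top=6, seed=0)
        se = ranked["importance_sd"] / np.sqrt(5)
        assert (ranked["importance_mean"].abs() <= 2 * se.clip(lower=0.01)).all()

    def test_duplicated_feature_shares_importance(self):
        rng = np.random.default_rng(10)
        n = 60
        labels = np.repeat([1, 2], n // 2)
        X = rng.standard_normal((n, 5))
        X[:, 0] = labels + 0.1 * rng.standard_normal(n)
        single = rf_importance(X, labels, n_seeds=3, n_trees=200, top=5, seed=1)
        single_imp = float(
            single.set_index("feature")["importance_mean"]["f0"]
        )
        X_dup = np.column_stack([X, X[:, 0]])
        dup = rf_importance(X_dup, labels, n_seeds=3, n_trees=200, top=6, seed=1)
        imp = dup.set_index("feature")["importance_mean"]
        assert imp["f0"] + imp["f5"] >= 0.5 * single_imp
        assert {dup["feature"].iloc[0], dup["feature"].iloc[1]} <= {"f0", "f5"}

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            rf_importance(np.zeros((10, 2)), np.ones(10))


def _brute_force_dominance(X, labels, alpha=0.05):
    """Independent reimplementation: plain loops over features and pairs."""
    clusters = sorted(set(labels.tolist()))
    pairs = [(a, b) for i, a in enumerate(clusters) for b in clusters[i + 1:]]
    counts = {c: np.zeros(X.shape[1], dtype=int) for c in clusters}
    for j in range(X.shape[1]):
        groups = [X[labels == c, j] for c in clusters]
        if stats.f_oneway(*groups).pvalue >= alpha:
            continue
        for a, b in pairs:
            ga, gb = X[labels == a, j], X[labels == b, j]
            if stats.ttest_ind(ga, gb).pvalue * len(pairs) < alpha:
                if np.median(ga) >= np.median(gb):
                    counts[a][j] += 1
                else:
                    counts[b][j] += 1
    return counts


class TestDominance:
    def test_two_cluster_separation_counted_once(self):
        rng = np.random.default_rng(11)
        labels = np.repeat([1, 2], 20)
        X = rng.standard_normal((40, 3))
        X[labels == 1, 0] += 10.0
        table = dominance(X, labels)
        assert table.counts.loc["f0", 1] == 1
        assert table.counts.loc["f0", 2] == 0

    def test_three_cluster_feature_wins_both_its_pairs(self):
        rng = np.random.default_rng(12)
        labels = np.repeat([1, 2, 3], 15)
        X = rng.standard_normal((45, 2))
        X[labels == 3, 1] += 8.0
        table = dominance(X, labels)
        assert table.counts.loc["f1", 3] == 2

    def test_pipeline_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(1, 4, 60)
        while np.bincount(labels)[1:].min() < 2:
            labels = rng.integers(1, 4, 60)
        X = rng.standard_normal((60, 10))
        X[labels == 2, 0] += 3.0
        X[labels == 1, 4] -= 2.0
        table = dominance(X, labels)
        brute = _brute_force_dominance(X, labels)
        for c in brute:
            np.testing.assert_array_equal(table.counts[c].to_numpy(), brute[c])

    def test_null_features_rarely_significant(self):
        # type-I control: identically distributed feature triggers the
        # ANOVA gate at roughly the nominal 5% rate
        rng = np.random.default_rng(14)
        labels = np.repeat([1, 2, 3], 10)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            x = rng.standard_normal(30)
            groups = [x[labels == c] for c in (1, 2, 3)]
            hits += stats.f_oneway(*groups).pvalue < 0.05
        assert 0.02 < hits / n_sim < 0.09

    def test_counts_only_for_anova_significant_features(self):
        rng = np.random.default_rng(15)
        labels = np.repeat([1, 2], 15)
        X = rng.standard_normal((30, 4))
        table = dominance(X, labels)
        for name in table.counts.index:
            if table.counts.loc[name].sum() > 0:
                assert table.anova_p[name] < 0.05


class TestSubtyping:
    def _exam(self, tremor, akinetic):
        items = {q: tremor for q in ("Q20", "Q21")}
        items.update({q: akinetic for q in ("Q22", "Q23", "Q24", "Q25", "Q26", "Q31")})
        return items

    def test_extreme_tremor_profile(self):
        assert eggers_classify(self._exam(4, 0)) == "tremor_dominant"

    def test_balanced_profile_is_mixed(self):
        assert eggers_classify(self._exam(2, 2)) == "mixed"

    def test_all_zero_exam_is_mixed_by_tie_rule(self):
        assert eggers_classify(self._exam(0, 0)) == "mixed"

    def test_extreme_akinetic_profile(self):
        assert eggers_classify(self._exam(0, 4)) == "akinetic_rigid"

    def test_missing_items_rejected(self):
        with pytest.raises(ValidationError):
            eggers_classify({"Q20": 1})

    def test_cohort_classification_covers_everyone(self):
        rng = np.random.default_rng(16)
        rows = []
        for i in range(20):
            rows.append({q: int(rng.integers(0, 5)) for q in
                         ("Q20", "Q21", "Q22", "Q23", "Q24", "Q25", "Q26", "Q31")})
        df = pd.DataFrame(rows)
        assign = classify_cohort(df)
        assert assign.labels.size == 20
        assert set(assign.labels) <= {1, 2, 3}


class TestComparePartitions:
    def test_identical_partitions_have_unit_ari(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((30, 4))
        labels = np.repeat([1, 2, 3], 10)
        a = ClusterAssignment(labels, 3, "a")
        b = ClusterAssignment(labels.copy(), 3, "b")
        out = compare_partitions(a, b, X)
        assert out["ari"] == 1.0
        assert out["silhouette_a"] == out["silhouette_b"]

    def test_random_labels_have_near_zero_mean_ari(self):
        rng = np.random.default_rng(18)
        truth = np.repeat([1, 2, 3], 20)
        aris = []
        for _ in range(100):
            perm = rng.permutation(truth)
            aris.append(
                compare_partitions(
                    ClusterAssignment(truth, 3, "t"),
                    ClusterAssignment(perm, 3, "p"),
                    rng.standard_normal((60, 2)),
                )["ari"]
            )
        assert abs(np.mean(aris)) < 0.02

    def test_single_cluster_against_many_gives_zero_ari(self):
        X = np.random.default_rng(19).standard_normal((30, 3))
        a = ClusterAssignment(np.ones(30, dtype=int), 1, "one")
        b = ClusterAssignment(np.repeat([1, 2, 3], 10), 3, "three")
        assert compare_partitions(a, b, X)["ari"] == 0.0

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_partitions(
                ClusterAssignment(np.ones(5, dtype=int), 1, "a"),
                ClusterAssignment(np.ones(6, dtype=int), 1, "b"),
                np.zeros((5, 2)),
            )
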