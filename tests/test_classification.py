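"""KDE Bayes classifier, RENN, imputation, selection, thresholds, voting."""

import numpy as np
import pandas as pd
import pytest

import drivercontext as dc


def two_clouds(rng, n_driver=30, n_passenger=30, gap=6.0, dim=1, sd=1.0):
    X = np.vstack([
        rng.normal(-gap / 2, sd, size=(n_driver, dim)),
        rng.normal(+gap / 2, sd, size=(n_passenger, dim)),
    ])
    y = np.array(["driver"] * n_driver + ["passenger"] * n_passenger)
    return X, y


class TestKdeClassifier:
    def test_balanced_priors(self, rng):
        X, y = two_clouds(rng)
        model = dc.kde_classifier_fit(X, y, (0.5, 1.0), seed=0)
        assert model.log_priors["driver"] == pytest.approx(np.log(0.5))

    def test_imbalanced_priors_are_class_fractions(self, rng):
        # the deployed model's pre-balancing shape: 544 drivers, 4005 passengers
        n_d, n_p = 544, 4005
        X = rng.normal(size=(n_d + n_p, 1))
        y = np.array(["driver"] * n_d + ["passenger"] * n_p)
        model = dc.kde_classifier_fit(X, y, (1.0,), seed=0)
        assert model.log_priors["driver"] == pytest.approx(np.log(n_d / (n_d + n_p)))

    def test_single_class_input_rejected(self, rng):
        X = rng.normal(size=(20, 1))
        with pytest.raises(ValueError):
            dc.kde_classifier_fit(X, ["driver"] * 20, (1.0,))

    def test_refit_same_seed_same_bandwidths(self, rng):
        X, y = two_clouds(rng, 40, 40)
        a = dc.kde_classifier_fit(X, y, (0.3, 1.0, 3.0), seed=5)
        b = dc.kde_classifier_fit(X, y, (0.3, 1.0, 3.0), seed=5)
        assert {c: m.bandwidth for c, m in a.class_models.items()} == \
               {c: m.bandwidth for c, m in b.class_models.items()}

    def test_midpoint_between_symmetric_clouds_is_half(self, rng):
        X, y = two_clouds(rng, 50, 50, gap=6.0, sd=0.5)
        # symmetrize exactly so the midpoint is truly equidistant
        X[50:] = -X[:50]
        model = dc.kde_classifier_fit(X, y, (0.5,), seed=0)
        assert model.posterior_driver([[0.0]])[0] == pytest.approx(0.5, abs=1e-9)

    def test_deep_inside_driver_cloud(self, rng):
        X, y = two_clouds(rng, 50, 50, gap=8.0, sd=0.5)
        model = dc.kde_classifier_fit(X, y, (0.5,), seed=0)
        assert model.posterior_driver([[-4.0]])[0] > 0.99

    def test_matches_brute_force_bayes_oracle(self):
        """Exhaustive likelihood*prior normalization on a 3-point fixture."""
        X = np.array([[0.0], [1.0], [5.0], [6.0], [7.0]])
        y = np.array(["driver", "driver", "passenger", "passenger", "passenger"])
        bw = 0.8
        model = dc.kde_classifier_fit(X, y, (bw,), seed=0)
        query = np.array([[0.5], [3.0], [6.5]])

        def gauss_lik(pts, x):
            z = (x - pts.ravel()) / bw
            return np.mean(np.exp(-0.5 * z**2) / (bw * np.sqrt(2 * np.pi)))

        for x in query.ravel():
            lik_d = gauss_lik(X[:2], x) * (2 / 5)
            lik_p = gauss_lik(X[2:], x) * (3 / 5)
            expected = lik_d / (lik_d + lik_p)
            got = dc.kde_classifier_posterior(model, [[x]])[0]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_posteriors_complement_to_one(self, rng):
        X, y = two_clouds(rng, 20, 20)
        model = dc.kde_classifier_fit(X, y, (1.0,), seed=0)
        post = model.posterior_driver(rng.normal(size=(30, 1)))
        assert np.all((post >= 0) & (post <= 1))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = two_clouds(rng, dim=2)
        model = dc.kde_classifier_fit(X, y, (1.0,), seed=0)
        with pytest.raises(ValueError):
            model.posterior_driver([[0.0]])


class TestRenn:
    def test_separated_clusters_are_a_fixed_point(self, rng):
        X, y = two_clouds(rng, 20, 60, gap=20.0, sd=0.3)
        Xr, yr = dc.renn_undersample(X, y, k=3)
        assert len(Xr) == len(X)

    def test_planted_intruder_removed(self, rng):
        X, y = two_clouds(rng, 20, 60, gap=20.0, sd=0.3)
        X = np.vstack([X, [[-10.0]]])               # majority point in minority cloud
        y = np.append(y, "passenger")
        Xr, yr = dc.renn_undersample(X, y, k=3)
        assert len(Xr) == len(X) - 1
        assert not np.any(np.isclose(Xr, -10.0))

    def test_minority_class_never_shrinks_and_output_is_subset(self, rng):
        X = rng.normal(size=(120, 2))
        y = np.array(["driver"] * 30 + ["passenger"] * 90)
        Xr, yr = dc.renn_undersample(X, y, k=3)
        assert np.sum(yr == "driver") == 30
        rows = {tuple(r) for r in X}
        assert all(tuple(r) in rows for r in Xr)

    def test_idempotent(self, rng):
        X = rng.normal(size=(100, 2))
        y = np.array(["driver"] * 25 + ["passenger"] * 75)
        X1, y1 = dc.renn_undersample(X, y, k=3)
        X2, y2 = dc.renn_undersample(X1, y1, k=3)
        assert len(X2) == len(X1)

    def test_k_too_large_rejected(self, rng):
        X, y = two_clouds(rng, 3, 3)
        with pytest.raises(ValueError):
            dc.renn_undersample(X, y, k=10)


class TestKnnImpute:
    def test_no_missing_is_identity(self, rng):
        X = rng.normal(size=(10, 3))
        out = dc.knn_impute(X, ["g"] * 10, k=2)
        np.testing.assert_array_equal(out, X)

    def test_single_same_gene_neighbor_copied(self):
        X = np.array([[1.0, 5.0], [1.0, np.nan], [50.0, 99.0]])
        out = dc.knn_impute(X, ["a", "a", "b"], k=1)
        assert out[1, 1] == 5.0

    def test_two_equidistant_neighbors_averaged(self):
        X = np.array([[0.0, 1.0], [2.0, 3.0], [1.0, np.nan]])
        out = dc.knn_impute(X, ["g", "g", "g"], k=2)
        assert out[2, 1] == 2.0

    def test_falls_back_to_global_pool_when_gene_too_small(self):
        X = np.array([[0.0, 10.0], [0.1, 20.0], [0.0, np.nan]])
        out = dc.knn_impute(X, ["a", "b", "c"], k=2)
        assert out[2, 1] == 15.0

    def test_all_missing_column_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError):
            dc.knn_impute(X, ["a", "a"], k=1)


class TestImpuritySelect:
    def test_label_copy_feature_ranked_first(self, rng):
        y = np.array(["driver"] * 40 + ["passenger"] * 40)
        X = rng.normal(size=(80, 10))
        X[:, 4] = (y == "driver").astype(float)
        names = [f"f{i}" for i in range(10)]
        selected = dc.impurity_select(X, y, mode="top_n", value=3, seed=0,
                                      feature_names=names)
        assert selected[0] == "f4"

    def test_top_n_returns_exactly_n(self, rng):
        y = np.array(["driver", "passenger"] * 30)
        X = rng.normal(size=(60, 200))
        assert len(dc.impurity_select(X, y, "top_n", 50, seed=0)) == 50

    def test_percentile_mode_keeps_stated_fraction(self, rng):
        y = np.array(["driver", "passenger"] * 30)
        X = rng.normal(size=(60, 40))
        assert len(dc.impurity_select(X, y, "percentile", 30, seed=0)) == 12

    def test_overlarge_n_clipped_with_warning(self, rng, caplog):
        y = np.array(["driver", "passenger"] * 10)
        X = rng.normal(size=(20, 5))
        selected = dc.impurity_select(X, y, "top_n", 50, seed=0)
        assert len(selected) == 5
        assert any("clipped" in r.message for r in caplog.records)

    def test_deterministic_under_seed(self, rng):
        y = np.array(["driver", "passenger"] * 25)
        X = rng.normal(size=(50, 30))
        assert dc.impurity_select(X, y, "top_n", 10, seed=3) == \
               dc.impurity_select(X, y, "top_n", 10, seed=3)


class TestThresholdAndVoting:
    def test_deployed_threshold_example(self):
        assert dc.apply_threshold(np.array([0.2]), 0.119)[0] == "driver"

    def test_threshold_one_labels_everything_passenger(self, rng):
        scores = rng.random(20)
        assert set(dc.apply_threshold(scores, 1.0)) == {"passenger"}

    def test_threshold_zero_labels_positive_scores_driver(self):
        labels = dc.apply_threshold(np.array([0.0, 0.001, 0.8]), 0.0)
        assert list(labels) == ["passenger", "driver", "driver"]

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            dc.apply_threshold(np.array([0.5]), 1.5)

    @pytest.mark.parametrize("calls,p,expected", [
        ([0, 0, 0, 1], 1, "driver"),
        ([1, 1, 1, 0], 4, "passenger"),
        ([1, 1, 0, 0], 2, "driver"),
    ])
    def test_at_least_p_rule(self, calls, p, expected):
        rule = dc.VoteRule("at_least_p", p=p)
        assert dc.vote(calls, rule) == expected

    def test_majority_rule_and_tie_goes_to_driver(self):
        assert dc.vote([1, 1, 0], dc.VoteRule("majority")) == "driver"
        assert dc.vote([1, 0], dc.VoteRule("majority")) == "driver"
        assert dc.vote([0, 0, 1], dc.VoteRule("majority")) == "passenger"

    def test_missing_member_call_rejected(self):
        with pytest.raises(ValueError):
            dc.vote([1, None, 0], dc.VoteRule("majority"))

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_at_least_majority_coincides_with_majority_on_odd_panels(self, n, rng):
        rule_p = dc.VoteRule("at_least_p", p=(n + 1) // 2)
        rule_m = dc.VoteRule("majority")
        for _ in range(20):
            calls = list(rng.integers(0, 2, n))
            assert dc.vote(calls, rule_p) == dc.vote(calls, rule_m)

    def test_vote_table_over_single_tool_is_identity(self):
        table = pd.DataFrame({"toolA": [1, 0, 1]}, index=["a", "b", "c"])
        rule = dc.VoteRule("at_least_p", p=1, member_names=("toolA",))
        out = dc.vote_table(table, rule)
        assert list(out) == ["driver", "passenger", "driver"]


@pytest.fixture(scope="module")
def trained(separable_benchmark):
    genome, mutations, descriptive = separable_benchmark
    config = dc.TrainConfig(
        encoding=dc.EncodingSpec("TF", 5, k=3),
        select_value=30, seed=2, threshold_folds=3)
    model = dc.train_driver_classifier(mutations, genome, descriptive, config)
    return genome, mutations, descriptive, model


class TestTrainPipeline:
    def test_selected_features_and_threshold_recorded(self, trained):
        _, _, _, model = trained
        assert len(model.selected_features) == 30
        assert 0.0 <= model.decision_threshold <= 1.0
        assert set(model.selected_features) <= set(model.feature_columns)

    def test_same_seed_reproduces_selected_features(self, separable_benchmark):
        genome, mutations, descriptive = separable_benchmark
        config = dc.TrainConfig(encoding=dc.EncodingSpec("CV", 3, k=2),
                                select_value=15, estimators=("kde",),
                                seed=7, threshold_folds=3)
        a = dc.train_driver_classifier(mutations, genome, descriptive, config)
        b = dc.train_driver_classifier(mutations, genome, descriptive, config)
        assert a.selected_features == b.selected_features
        assert a.decision_threshold == b.decision_threshold

    def test_neighborhood_only_model_trains_without_descriptive(self, separable_benchmark):
        genome, mutations, _ = separable_benchmark
        config = dc.TrainConfig(encoding=dc.EncodingSpec("CV", 3, k=2),
                                use_descriptive=False, select_value=15,
                                estimators=("kde",), seed=0, threshold_folds=3)
        model = dc.train_driver_classifier(mutations, genome, None, config)
        preds = model.predict_scores(mutations[:10], genome)
        assert set(preds["label"]) <= {"driver", "passenger"}

    def test_predictions_round_trip_through_archive(self, trained, tmp_path):
        genome, mutations, descriptive, model = trained
        model.save(tmp_path / "m.joblib")
        reloaded = dc.TrainedModel.load(tmp_path / "m.joblib")
        a = model.predict_scores(mutations[:15], genome, descriptive)
        b = reloaded.predict_scores(mutations[:15], genome, descriptive)
        pd.testing.assert_frame_equal(a, b)

    def test_unlabeled_training_data_rejected(self, separable_benchmark):
        genome, mutations, _ = separable_benchmark
        unlabeled = [dc.MutationRecord(m.chromosome, m.position, m.ref_base,
                                       m.alt_base) for m in mutations]
        with pytest.raises(ValueError):
            dc.train_driver_classifier(unlabeled, genome, None, dc.TrainConfig())
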