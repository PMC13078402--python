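"""Partitioning rules and the stacked single-instance ensemble."""

import numpy as np
import pytest

from otogene.data import FREQUENCIES
from otogene.ensemble import (
    PartitionedEnsembleClassifier,
    age_stratum,
    partition_training,
)
from otogene.preprocess import features_from_records

from conftest import flat_record, make_audiogram


class TestPartitioning:
    def test_age_boundaries_young_mid_old(self):
        assert age_stratum(19.9) == "young"
        assert age_stratum(20.0) == "mid"
        assert age_stratum(59.9) == "mid"
        assert age_stratum(60.0) == "old"

    def test_single_gene_dataset_is_one_volume_stratum(self):
        recs = [flat_record(pid=f"P{i}", age=30.0 + i) for i in range(4)]
        X, y, _ = features_from_records(recs)
        strata = partition_training(X, y)
        assert set(strata["volume"]) == {"high"}

    def test_balanced_genes_all_land_in_high_stratum(self):
        recs = []
        for g in ("WFS1", "KCNQ4", "COCH", "TECTA"):
            recs += [flat_record(pid=f"{g}{i}", gene=g, age=30.0 + i) for i in range(10)]
        X, y, _ = features_from_records(recs)
        strata = partition_training(X, y)
        assert set(strata["volume"]) == {"high"}  # all counts equal the median

    def test_minority_gene_lands_in_low_stratum(self):
        recs = [flat_record(pid=f"A{i}", gene="WFS1", age=30.0) for i in range(9)]
        recs += [flat_record(pid="B0", gene="KCNQ4", age=30.0)]
        X, y, _ = features_from_records(recs)
        strata = partition_training(X, y)
        assert set(strata["volume"][y == "KCNQ4"]) == {"low"}
        assert set(strata["volume"][y == "WFS1"]) == {"high"}

    def test_every_audiogram_reaches_an_age_stratum(self):
        recs = [flat_record(pid=f"P{i}", age=float(a)) for i, a in enumerate((5, 20, 45, 60, 95))]
        X, y, _ = features_from_records(recs)
        strata = partition_training(X, y)
        assert set(strata["age"]) <= {"young", "mid", "old"}
        assert len(strata["age"]) == 5


class TestEnsemble:
    def test_architecture_is_3_knn_6_ada_2_rf_plus_logistic(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        model = PartitionedEnsembleClassifier(random_state=0).fit(X, y)
        names = model.submodel_names_
        assert len(names) == 11
        assert sum(n.startswith("knn") for n in names) == 3
        assert sum(n.startswith("ada") for n in names) == 6
        assert sum(n.startswith("rf") for n in names) == 2
        from sklearn.linear_model import LogisticRegression

        assert isinstance(model.fuser_, LogisticRegression)

    def test_separable_two_gene_toy_reaches_perfect_training_accuracy(self, two_gene_cohort):
        # nearest-centroid oracle achieves 100% on this construction, so
        # the richer ensemble must too
        X, y, _ = features_from_records(two_gene_cohort)
        centroids = {g: X[y == g].mean(axis=0) for g in np.unique(y)}
        oracle = [min(centroids, key=lambda g: np.linalg.norm(x - centroids[g])) for x in X]
        assert (np.array(oracle) == y).all()
        model = PartitionedEnsembleClassifier(random_state=0).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_probabilities_form_a_distribution(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        model = PartitionedEnsembleClassifier(random_state=0).fit(X, y)
        panel_probs = model.predict_panel(X[:5])
        for d in panel_probs:
            assert len(d) == 23
            assert all(v >= 0 for v in d.values())
            assert sum(d.values()) == pytest.approx(1.0, abs=1e-9)

    def test_refit_same_seed_is_deterministic(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        p1 = PartitionedEnsembleClassifier(random_state=7).fit(X, y).predict_proba(X[:8])
        p2 = PartitionedEnsembleClassifier(random_state=7).fit(X, y).predict_proba(X[:8])
        np.testing.assert_array_equal(p1, p2)

    def test_training_row_order_does_not_change_predictions(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(y))
        p1 = PartitionedEnsembleClassifier(random_state=7).fit(X, y).predict_proba(X[:8])
        p2 = PartitionedEnsembleClassifier(random_state=7).fit(X[perm], y[perm]).predict_proba(X[:8])
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_singleton_class_excluded_with_warning(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        X = np.vstack([X, X[:1] + 1])
        y = np.append(y, "COCH")
        with pytest.warns(UserWarning, match="COCH"):
            model = PartitionedEnsembleClassifier(random_state=0).fit(X, y)
        assert model.excluded_classes_ == ["COCH"]
        assert "COCH" not in model.classes_

    def test_single_class_model_is_certain(self):
        recs = [flat_record(pid=f"P{i}", age=30.0 + i) for i in range(5)]
        X, y, _ = features_from_records(recs)
        model = PartitionedEnsembleClassifier(random_state=0).fit(X, y)
        probs = model.predict_audiogram(make_audiogram(age=50.0))
        assert probs["WFS1"] == pytest.approx(1.0)

    def test_save_load_round_trip_predicts_identically(self, two_gene_cohort, tmp_path):
        import joblib

        X, y, _ = features_from_records(two_gene_cohort)
        model = PartitionedEnsembleClassifier(random_state=0).fit(X, y)
        joblib.dump(model, tmp_path / "m.joblib")
        loaded = joblib.load(tmp_path / "m.joblib")
        np.testing.assert_array_equal(model.predict_proba(X[:6]), loaded.predict_proba(X[:6]))

    def test_top3_accuracy_high_when_separation_dominates_noise(self):
        # six flat genes whose means are >= 4x the noise SD apart
        rng = np.random.default_rng(12)
        sd = 4.0
        levels = {"WFS1": 0.0, "KCNQ4": 16.0, "COCH": 32.0,
                  "TECTA": 48.0, "MYO6": 64.0, "ACTG1": 80.0}
        X, y = [], []
        for g, mu in levels.items():
            for _ in range(40):
                age = rng.uniform(20, 60)
                thr = np.clip(mu + rng.normal(0, sd, 10), -10, 130)
                X.append(np.concatenate(([age], thr)))
                y.append(g)
        X, y = np.vstack(X), np.array(y, dtype=object)
        test = rng.permutation(len(y))[:60]
        train = np.setdiff1d(np.arange(len(y)), test)
        model = PartitionedEnsembleClassifier(random_state=0).fit(X[train], y[train])
        proba = model.predict_proba(X[test])
        top3 = np.argsort(proba, axis=1)[:, -3:]
        hits = [np.searchsorted(model.classes_, y[test][i]) in top3[i] for i in range(len(test))]
        assert np.mean(hits) >= 0.95

    def test_sklearn_params_round_trip(self):
        model = PartitionedEnsembleClassifier(knn_ks=(3, 7, 9), random_state=5)
        clone_params = model.get_params()
        assert clone_params["knn_ks"] == (3, 7, 9)
        model.set_params(rf_estimators=50)
        assert model.rf_estimators == 50
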