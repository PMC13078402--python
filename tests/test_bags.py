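"""Pairwise coupling (against a brute-force simplex oracle), bag
aggregation, and routing."""

import itertools

import numpy as np
import pytest

from otogene.bags import PairwiseCoupledBagClassifier, pairwise_coupling, route
from otogene.data import Audiogram, PatientRecord, FREQUENCIES
from otogene.ensemble import PartitionedEnsembleClassifier
from otogene.preprocess import features_from_records

from conftest import flat_record, make_audiogram


def brute_force_coupling(r: np.ndarray, resolution: float = 1e-4) -> np.ndarray:
    """Independent oracle: minimise the coupling KL objective by grid search
    over the probability simplex, coarse-to-fine down to ``resolution``.

    Objective (to minimise over p):  -sum_{i<j} [ r_ij*log(mu_ij) +
    (1-r_ij)*log(1-mu_ij) ]  with mu_ij = p_i/(p_i+p_j).
    """
    k = r.shape[0]
    pairs = list(itertools.combinations(range(k), 2))

    def neg_ll(p):
        total = 0.0
        for i, j in pairs:
            mu = p[i] / (p[i] + p[j])
            mu = min(max(mu, 1e-12), 1 - 1e-12)
            total -= r[i, j] * np.log(mu) + (1 - r[i, j]) * np.log(1 - mu)
        return total

    def grid(center, half_width, step):
        axes = [np.arange(max(c - half_width, 1e-9), min(c + half_width, 1.0) + step / 2, step)
                for c in center[:-1]]
        best, best_val = None, np.inf
        for combo in itertools.product(*axes):
            last = 1.0 - sum(combo)
            if last <= 1e-9:
                continue
            p = np.array(combo + (last,))
            v = neg_ll(p)
            if v < best_val:
                best, best_val = p, v
        return best

    p = grid(np.full(k, 1.0 / k), 0.5, 0.02)
    for step in (2e-3, resolution):
        p = grid(p, 10 * step, step)
    return p


class TestPairwiseCoupling:
    def test_binary_case_reproduces_input_exactly(self):
        probs = pairwise_coupling({("A", "B"): 0.7}, ["A", "B"])
        assert probs["A"] == pytest.approx(0.7, abs=1e-8)
        assert probs["B"] == pytest.approx(0.3, abs=1e-8)

    def test_all_even_pairs_give_uniform_distribution(self):
        table = {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5}
        probs = pairwise_coupling(table, ["A", "B", "C"])
        for v in probs.values():
            assert v == pytest.approx(1 / 3, abs=1e-8)

    def test_output_is_a_distribution(self):
        table = {("A", "B"): 0.9, ("A", "C"): 0.2, ("B", "C"): 0.6}
        probs = pairwise_coupling(table, ["A", "B", "C"])
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v > 0 for v in probs.values())

    def test_missing_pair_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            pairwise_coupling({("A", "B"): 0.7}, ["A", "B", "C"])

    @pytest.mark.parametrize("k,seed", [(3, 0), (3, 1), (4, 2), (4, 3)])
    def test_fixed_point_matches_brute_force_simplex_search(self, k, seed):
        rng = np.random.default_rng(seed)
        classes = [f"G{i}" for i in range(k)]
        table = {}
        r = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                p = float(rng.uniform(0.1, 0.9))
                table[(classes[i], classes[j])] = p
                r[i, j], r[j, i] = p, 1 - p
        coupled = pairwise_coupling(table, classes)
        oracle = brute_force_coupling(r)
        got = np.array([coupled[c] for c in classes])
        assert np.max(np.abs(got - oracle)) < 1e-3


class TestBagClassifier:
    def test_pairwise_accuracy_on_separable_toy(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        model = PairwiseCoupledBagClassifier(random_state=0).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_refit_same_seed_reproduces_probabilities(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        p1 = PairwiseCoupledBagClassifier(random_state=1).fit(X, y).predict_proba(X[:5])
        p2 = PairwiseCoupledBagClassifier(random_state=1).fit(X, y).predict_proba(X[:5])
        np.testing.assert_allclose(p1, p2)

    def test_identical_class_distributions_calibrate_near_half(self):
        # two classes drawn from the same distribution: the calibrated
        # pairwise probability should hover around 0.5
        rng = np.random.default_rng(8)
        X = np.column_stack([rng.uniform(20, 60, 200),
                             *(rng.normal(40, 10, (10, 200)))]).reshape(200, 11)
        y = np.array(["A"] * 100 + ["B"] * 100, dtype=object)
        model = PairwiseCoupledBagClassifier(random_state=0).fit(X, y)
        probs = model.predict_proba(X)
        assert abs(probs[:, 0].mean() - 0.5) < 0.1

    def test_bag_of_one_equals_single_instance_prediction(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        model = PairwiseCoupledBagClassifier(random_state=0).fit(X, y)
        rec = two_gene_cohort[0]
        bag_probs = model.predict_bag(rec)
        row = model.predict_proba(X[:1])[0]
        for g, p in zip(model.classes_, row):
            assert bag_probs[str(g)] == pytest.approx(p, abs=1e-12)

    def test_duplicated_instance_does_not_change_the_bag(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        model = PairwiseCoupledBagClassifier(random_state=0).fit(X, y)
        a = two_gene_cohort[0].audiograms[0]
        one = model.predict_bag(PatientRecord("P", [a]))
        two = model.predict_bag(PatientRecord("P", [a, a]))
        for g in one:
            assert one[g] == pytest.approx(two[g], abs=1e-12)

    def test_bag_order_permutation_invariance(self, two_gene_cohort):
        X, y, _ = features_from_records(two_gene_cohort)
        model = PairwiseCoupledBagClassifier(random_state=0).fit(X, y)
        a, b = two_gene_cohort[0].audiograms[0], two_gene_cohort[1].audiograms[0]
        p_ab = model.predict_bag(PatientRecord("P", [a, b]))
        p_ba = model.predict_bag(PatientRecord("P", [b, a]))
        assert p_ab == pytest.approx(p_ba)

    def test_coupling_agrees_with_libsvm_reference_on_toy(self, two_gene_cohort):
        # independent cross-check: sklearn's SVC(probability=True) runs
        # libsvm's own Platt + coupling; on a cleanly separable toy both
        # routes must give the same top class everywhere
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X, y, _ = features_from_records(two_gene_cohort)
        ours = PairwiseCoupledBagClassifier(random_state=0).fit(X, y)
        ref = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", probability=True, random_state=0)),
        ]).fit(X, y)
        np.testing.assert_array_equal(ours.predict(X), ref.predict(X))


@pytest.fixture(scope="module")
def models(two_gene_cohort):
    X, y, _ = features_from_records(two_gene_cohort)
    si = PartitionedEnsembleClassifier(random_state=0).fit(X, y)
    mi = PairwiseCoupledBagClassifier(random_state=0).fit(X, y)
    return si, mi


class TestRouting:

    @pytest.mark.parametrize("n_audiograms,expected", [(1, "single_instance"),
                                                       (2, "multi_instance"),
                                                       (3, "multi_instance")])
    def test_bag_size_routes_to_the_right_engine(self, models, n_audiograms, expected):
        si, mi = models
        rec = flat_record(level=20.0, gene="WFS1", n_audiograms=n_audiograms)
        route_name, probs = route(rec, si, mi)
        assert route_name == expected
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
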