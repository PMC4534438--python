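import warnings

import numpy as np
import pytest

import pulmoquest as pq
from pulmoquest.classifiers import (
    ALL_KINDS,
    DETERMINISTIC_KINDS,
    FUZZY,
    NAIVE_BAYES,
    NEAREST_NEIGHBOUR,
    RANDOM_FOREST,
    fuzzy_predict,
    fuzzy_train,
    load_model,
    save_model,
)
from pulmoquest.core import DIAGNOSES, Cohort, ConfigurationError

from conftest import record, small_spec, uniform_answers
from oracles import naive_bayes_posterior


def _train_quiet(kind, cohort, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pq.train(kind, cohort, **kw)


@pytest.fixture(scope="module")
def probe():
    rng = np.random.default_rng(42)
    return tuple(int(v) for v in rng.integers(1, 7, size=45))


class TestBankContract:
    def test_exactly_eight_kinds(self):
        assert len(ALL_KINDS) == 8
        assert set(ALL_KINDS) == {
            "SVM", "ANN", "FUZZY", "RANDOM_FOREST", "LOGISTIC",
            "LDA", "NAIVE_BAYES", "NEAREST_NEIGHBOUR",
        }

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_output_is_valid_probability_vector(self, kind, three_class_cohort, probe):
        model = _train_quiet(kind, three_class_cohort, seed=1)
        p = pq.predict_proba(model, probe)
        assert p.shape == (7,)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert abs(p.sum() - 1.0) < 1e-9

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_absent_classes_get_probability_exactly_zero(self, kind, three_class_cohort, probe):
        model = _train_quiet(kind, three_class_cohort, seed=1)
        p = pq.predict_proba(model, probe)
        for absent in ("PM", "AB", "PBB", "CTRL"):
            assert p[DIAGNOSES.index(absent)] == 0.0

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_single_class_cohort_degenerates_to_certainty(self, kind, probe):
        cohort = Cohort([record(f"r{i}", uniform_answers(2), "PM") for i in range(4)])
        model = _train_quiet(kind, cohort, seed=0)
        p = pq.predict_proba(model, probe)
        assert p[DIAGNOSES.index("PM")] == 1.0

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_identical_inputs_and_seed_reproduce_predictions(self, kind, three_class_cohort, probe):
        p1 = pq.predict_proba(_train_quiet(kind, three_class_cohort, seed=5), probe)
        p2 = pq.predict_proba(_train_quiet(kind, three_class_cohort, seed=5), probe)
        assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("kind", DETERMINISTIC_KINDS)
    def test_training_order_invariance_for_deterministic_kinds(self, kind, three_class_cohort, probe):
        records = list(three_class_cohort.records)
        shuffled = [records[i] for i in np.random.default_rng(8).permutation(len(records))]
        p1 = pq.predict_proba(_train_quiet(kind, three_class_cohort), probe)
        p2 = pq.predict_proba(_train_quiet(kind, Cohort(shuffled)), probe)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_random_forest_fits_separable_cohort(self, sep095_cohort):
        model = _train_quiet(RANDOM_FOREST, sep095_cohort, seed=7)
        correct = sum(
            DIAGNOSES[int(np.argmax(pq.predict_proba(model, r.answers)))] == r.label
            for r in sep095_cohort
        )
        assert correct / len(sep095_cohort) >= 0.9

    def test_missing_answers_are_imputed_at_prediction(self, three_class_cohort):
        model = _train_quiet(NAIVE_BAYES, three_class_cohort)
        full = pq.predict_proba(model, pq.impute_missing((None,) * 45, model.imputation_reference))
        holey = pq.predict_proba(model, (None,) * 45)
        assert np.allclose(full, holey)

    def test_errors(self, three_class_cohort):
        with pytest.raises(ConfigurationError):
            pq.train("DECISION_TABLE", three_class_cohort)
        with pytest.raises(ValueError):
            pq.train(NAIVE_BAYES, Cohort([]))
        model = _train_quiet(NAIVE_BAYES, three_class_cohort)
        with pytest.raises(ValueError, match="44"):
            pq.predict_proba(model, (3,) * 44)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_standalone_cv_accuracy_beats_chance_threefold(self, kind, cv_report_sep095):
        table = pq.sensitivity_table(cv_report_sep095)
        assert table.loc[kind, "overall"] > 3 / 7


class TestNearestNeighbour:
    def test_exact_training_copy_wins_outright(self, three_class_cohort):
        rec = three_class_cohort.records[0]
        for k in (1, 5):
            model = _train_quiet(
                NEAREST_NEIGHBOUR, three_class_cohort, hyperparameters={"k": k}
            )
            p = pq.predict_proba(model, rec.answers)
            assert p[DIAGNOSES.index(rec.label)] == pytest.approx(1.0)


class TestNaiveBayes:
    def test_hand_computed_two_class_toy(self):
        # classes CF,CF,AS,AS; q1 answers 1,1,2,2; all other answers 3.
        # Query q1=1: posterior CF = (3/8) / (3/8 + 1/8) = 0.75.
        recs = [
            record("a", (1,) + (3,) * 44, "CF"),
            record("b", (1,) + (3,) * 44, "CF"),
            record("c", (2,) + (3,) * 44, "AS"),
            record("d", (2,) + (3,) * 44, "AS"),
        ]
        model = _train_quiet(NAIVE_BAYES, Cohort(recs))
        p = pq.predict_proba(model, (1,) + (3,) * 44)
        assert p[DIAGNOSES.index("CF")] == pytest.approx(0.75, abs=1e-9)
        assert p[DIAGNOSES.index("AS")] == pytest.approx(0.25, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_smoothed_frequency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        labels = rng.choice(["CF", "AS", "PBB"], size=n)
        if len(set(labels)) < 2:
            labels[0] = "CF" if labels[0] != "CF" else "AS"
        recs = [
            record(f"r{i}", tuple(int(v) for v in rng.integers(1, 7, 45)), labels[i])
            for i in range(n)
        ]
        cohort = Cohort(recs)
        model = _train_quiet(NAIVE_BAYES, cohort)
        for _ in range(3):
            query = tuple(int(v) for v in rng.integers(1, 7, 45))
            assert np.allclose(
                pq.predict_proba(model, query),
                naive_bayes_posterior(cohort, query),
                atol=1e-9,
            )


class TestFuzzy:
    def test_membership_rescaled_to_peak_one(self):
        cohort = Cohort([record(f"r{i}", (4,) + (2,) * 44, "CF") for i in range(5)])
        model = fuzzy_train(cohort)
        memb = model.estimator.memberships_  # (classes, questions, levels)
        assert memb[0, 0, 3] == pytest.approx(1.0)
        assert memb[0, 0, 0] < 1.0

    def test_disjoint_modes_favour_matching_class(self):
        recs = [record(f"a{i}", (1,) * 45, "CF") for i in range(5)]
        recs += [record(f"b{i}", (6,) * 45, "AS") for i in range(5)]
        model = fuzzy_train(Cohort(recs))
        p = fuzzy_predict(model, (1,) * 45)
        assert p[DIAGNOSES.index("CF")] > 0.5

    def test_identical_training_answers_give_symmetric_posterior(self):
        recs = [record(f"a{i}", (3,) * 45, "CF") for i in range(4)]
        recs += [record(f"b{i}", (3,) * 45, "AS") for i in range(4)]
        p = fuzzy_predict(fuzzy_train(Cohort(recs)), (5,) * 45)
        assert p[DIAGNOSES.index("CF")] == pytest.approx(0.5, abs=1e-9)
        assert p[DIAGNOSES.index("AS")] == pytest.approx(0.5, abs=1e-9)

    def test_fuzzy_predict_rejects_other_kinds(self, three_class_cohort):
        model = _train_quiet(NAIVE_BAYES, three_class_cohort)
        with pytest.raises(ConfigurationError):
            fuzzy_predict(model, uniform_answers())


class TestPersistence:
    def test_roundtrip_preserves_predictions(self, three_class_cohort, tmp_path, probe):
        model = _train_quiet(FUZZY, three_class_cohort)
        path = tmp_path / "model.bin"
        save_model(model, str(path))
        loaded = load_model(str(path))
        assert loaded.kind == FUZZY
        assert np.allclose(pq.predict_proba(loaded, probe), pq.predict_proba(model, probe))

    def test_foreign_version_fails_loudly(self, three_class_cohort, tmp_path):
        import pickle

        model = _train_quiet(FUZZY, three_class_cohort)
        path = tmp_path / "model.bin"
        save_model(model, str(path))
        payload = pickle.load(open(path, "rb"))
        payload["package_version"] = "0.0.0-other"
        pickle.dump(payload, open(path, "wb"))
        with pytest.raises(ConfigurationError, match="version"):
            load_model(str(path))
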