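"""Feature assembly, patient-grouped splitting, selection/training,
metrics and rater agreement."""

import numpy as np
import pandas as pd
import pytest

from oomech.classify import (assemble_features, split_by_patient,
                             train_test_target_sizes, forward_select_and_train,
                             evaluate, confusion_metrics, fleiss_kappa,
                             compare_predictors, FeatureTable, DataError)
from conftest import true_fits


@pytest.fixture(scope="module")
def separated_table(separated_cohort):
    return assemble_features(separated_cohort, true_fits(separated_cohort),
                             "mechanical", fertilized_only=True)


class TestAssembleFeatures:
    def test_maternal_set_has_two_columns(self, separated_cohort):
        t = assemble_features(separated_cohort, true_fits(separated_cohort),
                              "maternal")
        assert t.feature_names == ["patient_age", "mii_count"]

    def test_mechanical_set_columns_and_tau(self, separated_table):
        assert set(separated_table.feature_names) == {"k0", "k1", "eta0",
                                                      "eta1", "tau"}

    def test_excluded_oocytes_are_logged(self, separated_cohort):
        t = assemble_features(separated_cohort, true_fits(separated_cohort),
                              "mechanical")
        n_video = int(separated_cohort["excluded"].sum())
        assert (t.excluded["reason"] == "poor video quality").sum() == n_video
        assert len(t.y) + n_video == int((separated_cohort.arm == "measured").sum())

    def test_nonpositive_feature_is_data_error(self, separated_cohort):
        fits = true_fits(separated_cohort)
        fits.loc[fits.index[0], "k0"] = -1.0
        with pytest.raises(DataError):
            assemble_features(separated_cohort, fits, "mechanical")

    def test_standardized_training_columns(self, separated_table):
        split = split_by_patient(separated_table, seed=0)
        separated_table.fit_scaler(split.train_index)
        Xs = separated_table.transform(split.train_index)
        assert np.allclose(Xs.mean(), 0.0, atol=1e-10)
        assert np.allclose(Xs.std(ddof=0), 1.0, atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 1, 1, 1]},
                         index=list("wxyz"))
        t = FeatureTable(X=X, y=pd.Series([0, 1, 0, 1], index=list("wxyz")),
                         patient_id=pd.Series(["p", "p", "q", "q"],
                                              index=list("wxyz")))
        with pytest.warns(UserWarning, match="zero-variance"):
            t.fit_scaler(list("wxyz"))
        assert t.feature_names == ["a"]


class TestSplitByPatient:
    def test_published_style_rounding(self):
        # ~70/30 of 209 oocytes -> 146 train / 63 test; of 160 -> 112 / 48
        assert train_test_target_sizes(209, 0.7) == (146, 63)
        assert train_test_target_sizes(160, 0.7) == (112, 48)

    def test_even_patients_split_exactly(self):
        cohort = pd.DataFrame({
            "patient_id": np.repeat([f"P{i}" for i in range(10)], 10),
            "oocyte_id": [f"o{i}" for i in range(100)]})
        s = split_by_patient(cohort, 0.7, seed=0)
        assert len(s.train_index) == 70 and len(s.test_index) == 30
        assert len(s.train_patients) == 7

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_patients_never_straddle(self, separated_table, seed):
        s = split_by_patient(separated_table, seed=seed)
        assert not (s.train_patients & s.test_patients)
        pid = separated_table.patient_id
        assert set(pid.loc[s.train_index]) == s.train_patients
        assert set(pid.loc[s.test_index]) == s.test_patients

    def test_greedy_lands_near_target(self, separated_table):
        s = split_by_patient(separated_table, 0.7, seed=5)
        target, _ = train_test_target_sizes(len(separated_table.y), 0.7)
        max_patient = separated_table.patient_id.value_counts().max()
        assert abs(len(s.train_index) - target) <= max_patient

    def test_single_patient_is_error(self):
        cohort = pd.DataFrame({"patient_id": ["P0"] * 5,
                               "oocyte_id": list("abcde")})
        with pytest.raises(ValueError):
            split_by_patient(cohort)


class TestForwardSelectionAndTraining:
    def test_separating_feature_selected_first(self):
        rng = np.random.default_rng(0)
        n = 120
        y = rng.random(n) < 0.5
        X = pd.DataFrame({
            "signal": np.where(y, 3.0, 1.0) * np.exp(rng.normal(0, 0.05, n)),
            "noise1": np.exp(rng.normal(0, 1, n)),
            "noise2": np.exp(rng.normal(0, 1, n)),
        }, index=[f"o{i}" for i in range(n)])
        pid = pd.Series(np.repeat([f"P{i}" for i in range(12)], 10), index=X.index)
        t = FeatureTable(X=np.log2(X), y=pd.Series(y, index=X.index),
                         patient_id=pid)
        s = split_by_patient(t, seed=0)
        clf = forward_select_and_train(t, s, seed=0)
        assert clf.cv_report["steps"][0]["added"] == "signal"
        assert evaluate(clf, s).acc > 90

    def test_mechanical_selection_is_subset_of_mechanics(self, separated_table):
        s = split_by_patient(separated_table, seed=1)
        clf = forward_select_and_train(separated_table, s, seed=1)
        assert set(clf.features) <= {"tau", "k0", "k1", "eta0", "eta1"}

    def test_deterministic_given_seed(self, separated_table):
        s = split_by_patient(separated_table, seed=2)
        a = forward_select_and_train(separated_table, s, seed=2)
        b = forward_select_and_train(separated_table, s, seed=2)
        assert a.features == b.features and a.cv_report == b.cv_report

    def test_no_leakage_from_test_labels(self, separated_cohort):
        # perturbing test labels must change nothing about training
        t1 = assemble_features(separated_cohort, true_fits(separated_cohort),
                               "mechanical", fertilized_only=True)
        s = split_by_patient(t1, seed=3)
        t2 = assemble_features(separated_cohort, true_fits(separated_cohort),
                               "mechanical", fertilized_only=True)
        t2.y.loc[s.test_index] = ~t2.y.loc[s.test_index]
        a = forward_select_and_train(t1, s, seed=3)
        b = forward_select_and_train(t2, s, seed=3)
        assert a.features == b.features and a.cv_report == b.cv_report
        assert np.array_equal(a.model.dual_coef_, b.model.dual_coef_)
        assert a.table.mean_.equals(b.table.mean_)

    def test_single_class_training_is_error(self):
        X = pd.DataFrame({"a": np.arange(20.0)}, index=[f"o{i}" for i in range(20)])
        t = FeatureTable(X=X, y=pd.Series(True, index=X.index),
                         patient_id=pd.Series(np.repeat(["p", "q", "r", "s"], 5),
                                              index=X.index))
        s = split_by_patient(t, seed=0)
        with pytest.raises(ValueError):
            forward_select_and_train(t, s)


class TestConfusionMetrics:
    def test_arithmetic_oracle(self):
        m = confusion_metrics([1] * 12 + [0] * 8,
                              [1] * 8 + [0] * 4 + [1] * 2 + [0] * 6)
        assert (m.tp, m.fn, m.fp, m.tn) == (8, 4, 2, 6)
        assert m.acc == pytest.approx(70.0)
        assert m.ppv == pytest.approx(80.0)
        assert m.npv == pytest.approx(60.0)
        assert m.sen == pytest.approx(100 * 8 / 12)
        assert m.spe == pytest.approx(75.0)

    def test_perfect_predictions(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert [m.acc, m.ppv, m.npv, m.sen, m.spe] == [100.0] * 5

    def test_all_positive_predictor(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 1, 1, 1])
        assert m.sen == 100.0 and m.spe == 0.0
        assert "npv" in m.undefined  # tn + fn == 0: flagged, not zeroed


def longhand_fleiss(matrix: np.ndarray) -> float:
    """Independent longhand kappa: per-subject agreement and squared
    marginal category proportions, straight from the definition."""
    cats = sorted({v for row in matrix for v in row})
    n_sub, n_rat = matrix.shape
    counts = np.array([[sum(v == c for v in row) for c in cats] for row in matrix])
    P_i = ((counts ** 2).sum(axis=1) - n_rat) / (n_rat * (n_rat - 1))
    p_j = counts.sum(axis=0) / (n_sub * n_rat)
    Pbar, Pe = P_i.mean(), (p_j ** 2).sum()
    return (Pbar - Pe) / (1 - Pe)


class TestFleissKappa:
    def test_perfect_agreement(self):
        m = np.array([["u"] * 4, ["x"] * 4] * 3)
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_matches_longhand_on_constructed_table(self):
        rng = np.random.default_rng(42)
        m = rng.choice(["usable", "unusable"], size=(12, 4))
        assert fleiss_kappa(m) == pytest.approx(longhand_fleiss(m), abs=1e-12)

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        m = rng.choice(["u", "x"], size=(500, 4))
        assert abs(fleiss_kappa(m)) < 0.05

    def test_degenerate_unanimous_single_category(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([["u"] * 4] * 6))

    def test_incomplete_matrix_rejected(self):
        m = pd.DataFrame([["u", None], ["x", "u"]])
        with pytest.raises(ValueError):
            fleiss_kappa(m)


class TestComparePredictors:
    def test_mean_rater_accuracy(self):
        # four raters at exactly 38/42/50/44 percent accuracy average 43.5
        n = 100
        idx = [f"o{i}" for i in range(n)]
        y = pd.Series([True] * 50 + [False] * 50, index=idx)
        preds = {}
        for name, acc in zip("Emb1 Emb2 Emb3 Emb4".split(), (38, 42, 50, 44)):
            p = y.copy()
            p.iloc[acc:] = ~p.iloc[acc:]  # flip n-acc of them
            preds[name] = p
        out = compare_predictors({}, pd.DataFrame(preds), y_true=y)
        mean_row = out[out.predictor == "mean_rater"].iloc[0]
        assert mean_row.acc == pytest.approx(43.5)
        assert round(mean_row.acc) == 44

    def test_mechanical_beats_maternal_on_separated_cohort(self, separated_cohort):
        # maternal factors are independent of the label by construction
        fits = true_fits(separated_cohort)
        variants = {}
        for fs in ("mechanical", "maternal"):
            t = assemble_features(separated_cohort, fits, fs, fertilized_only=True)
            s = split_by_patient(t, seed=4)
            variants[fs] = (forward_select_and_train(t, s, seed=4), s)
        out = compare_predictors(variants).set_index("predictor")
        assert out.loc["mechanical", "acc"] > out.loc["maternal", "acc"]

    def test_mismatched_test_sets_rejected(self, separated_table):
        s1 = split_by_patient(separated_table, seed=0)
        s2 = split_by_patient(separated_table, seed=9)
        c1 = forward_select_and_train(separated_table, s1, seed=0)
        if set(s1.test_index) == set(s2.test_index):
            pytest.skip("seeds produced identical splits")
        with pytest.raises(ValueError):
            compare_predictors({"a": (c1, s1), "b": (c1, s2)})
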