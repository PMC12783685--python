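"""Linear probes, incremental dose aggregation, MoA metrics, McNemar."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcd.moa import (
    ConditionPredictions,
    SingleClassError,
    assign_folds,
    cross_validate,
    evaluate_moa,
    incremental_aggregate,
    mcnemar_test,
    predict_conditions,
    train_probe,
)
from lcd.schema import ProfileTable

from conftest import make_profile_frame


def _probe_table(n_per_class=6, sep=6.0, seed=0, D=4):
    """Linearly separable 2-MoA + DMSO table at one condition."""
    rng = np.random.default_rng(seed)
    rows, X = [], []
    centers = {"DMSO": np.zeros(D)}
    centers["MoA-A"] = np.r_[sep, np.zeros(D - 1)]
    centers["MoA-B"] = np.r_[0.0, sep, np.zeros(D - 2)]
    i = 0
    for label, cpds in [("DMSO", ["DMSO"]), ("MoA-A", ["A1", "A2"]), ("MoA-B", ["B1", "B2"])]:
        for cpd in cpds:
            for _ in range(n_per_class):
                rows.append(
                    {
                        "Metadata_well": f"{chr(ord('A') + i // 24)}{i % 24 + 1:02d}",
                        "Metadata_fov": 1,
                        "Metadata_compound": cpd,
                        "Metadata_dose_uM": None if cpd == "DMSO" else 2.5,
                        "Metadata_moa": None if cpd == "DMSO" else label,
                        "Metadata_role": "negative_control" if cpd == "DMSO" else "treatment",
                    }
                )
                X.append(centers[label] + rng.normal(0, 0.3, D))
                i += 1
    df = make_profile_frame(rows, feature_names=())
    X = np.asarray(X)
    for j in range(D):
        df[f"f{j}"] = X[:, j]
    return ProfileTable(df)


class TestTrainProbe:
    def test_separable_data_training_accuracy_one(self):
        table = _probe_table()
        probe = train_probe(table, 2.5, 20.0, seed=0)
        sl = table.data
        proba = probe.predict_proba(table.features)
        pred = [probe.class_labels[i] for i in proba.argmax(axis=1)]
        truth = np.where(sl["Metadata_compound"] == "DMSO", "DMSO", sl["Metadata_moa"])
        assert (np.asarray(pred) == truth).mean() == 1.0

    def test_refit_same_seed_identical_weights(self):
        table = _probe_table()
        a = train_probe(table, 2.5, 20.0, seed=3)
        b = train_probe(table, 2.5, 20.0, seed=3)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.intercepts, b.intercepts)

    def test_pure_noise_predicts_near_prior(self):
        rng = np.random.default_rng(1)
        table = _probe_table(sep=0.0, n_per_class=30, seed=1)
        probe = train_probe(table, 2.5, 20.0, seed=1)
        proba = probe.predict_proba(rng.normal(0, 0.3, (500, 4)))
        # with no signal, accuracy on fresh noise cannot beat the max prior by much
        pred = np.array([probe.class_labels[i] for i in proba.argmax(axis=1)])
        # priors: DMSO 30, A 60, B 60 wells -> max prior = 0.4
        acc_vs_any = max((pred == c).mean() for c in probe.class_labels)
        assert acc_vs_any < 0.75

    def test_single_class_rejected(self):
        table = _probe_table()
        with pytest.raises(SingleClassError):
            train_probe(table, 2.5, 20.0, active_compounds=set(), seed=0)


class TestPredictConditions:
    def test_rows_sum_to_one_and_single_well_equals_softmax(self):
        table = _probe_table(n_per_class=1)
        probe = train_probe(_probe_table(), 2.5, 20.0, seed=0)
        preds = predict_conditions(probe, table)
        p = preds.probabilities.to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        # one well per compound: row equals the probe softmax on that well
        sl = table.data[table.data["Metadata_compound"] == "A1"]
        direct = probe.predict_proba(sl[table.feature_names].to_numpy())[0]
        np.testing.assert_allclose(preds.probabilities.loc["A1"].to_numpy(), direct, atol=1e-12)

    def test_class_alignment_pads_with_zero(self):
        table = _probe_table()
        probe = train_probe(table, 2.5, 20.0, seed=0)
        preds = predict_conditions(probe, table, class_labels=probe.class_labels + ["MoA-X"])
        assert (preds.probabilities["MoA-X"] == 0).all()


def _preds(cond, data):
    frame = pd.DataFrame(data).T
    frame.columns = ["x", "y"]
    frame.index.name = "compound"
    return ConditionPredictions(cond, frame)


class TestIncrementalAggregate:
    def test_single_condition_identity(self):
        p = _preds((1.0, 4.0), {"C1": [0.7, 0.3]})
        out = incremental_aggregate([p], [1.0], 0)
        np.testing.assert_allclose(out.loc["C1", ["x", "y"]].astype(float), [0.7, 0.3])
        assert out.loc["C1", "label"] == "x"

    def test_zero_weight_ignores_condition(self):
        a = _preds((1.0, 4.0), {"C1": [1.0, 0.0]})
        b = _preds((2.0, 4.0), {"C1": [0.0, 1.0]})
        out = incremental_aggregate([a, b], [1.0, 2.0], 1, weights=[1.0, 0.0])
        np.testing.assert_allclose(out.loc["C1", ["x", "y"]].astype(float), [1.0, 0.0])

    def test_identical_predictions_unchanged(self):
        a = _preds((1.0, 4.0), {"C1": [0.6, 0.4]})
        b = _preds((2.0, 4.0), {"C1": [0.6, 0.4]})
        out = incremental_aggregate([a, b], [1.0, 2.0], 1)
        np.testing.assert_allclose(out.loc["C1", ["x", "y"]].astype(float), [0.6, 0.4])

    def test_empty_inclusion_rejected(self):
        a = _preds((2.0, 4.0), {"C1": [0.6, 0.4]})
        with pytest.raises(ValueError, match="no conditions"):
            incremental_aggregate([a], [1.0, 2.0], 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_aggregation_preserves_simplex(self, seed):
        rng = np.random.default_rng(seed)
        conds = [(d, t) for d in (1.0, 2.0) for t in (4.0, 8.0)]
        preds = []
        for cond in conds:
            p = rng.dirichlet(np.ones(3), size=2)
            frame = pd.DataFrame(p, index=["C1", "C2"], columns=["a", "b", "c"])
            frame.index.name = "compound"
            preds.append(ConditionPredictions(cond, frame))
        w = rng.uniform(0.1, 2.0, size=len(conds))
        out = incremental_aggregate(preds, [1.0, 2.0], 1, weights=list(w))
        vals = out[["a", "b", "c"]].to_numpy(dtype=float)
        assert (vals >= -1e-12).all()
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-9)


class TestEvaluateMoa:
    def test_perfect_predictions(self):
        df = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [0.0, 1.0], "label": ["a", "b"], "top3": [["a", "b"], ["b", "a"]]},
            index=["C1", "C2"],
        )
        rep = evaluate_moa(df, {"C1": "a", "C2": "b"}, ["DMSO", "a", "b"])
        assert rep.f1_weighted == rep.accuracy == rep.top3_accuracy == 1.0
        cm = rep.confusion_matrix
        assert np.trace(cm.to_numpy()) == 2 and cm.to_numpy().sum() == 2

    def test_constant_prediction_on_balanced_truth(self):
        classes = [f"m{i}" for i in range(10)]
        df = pd.DataFrame(
            {"label": ["m0"] * 10, "top3": [["m0", "m1", "m2"]] * 10},
            index=[f"C{i}" for i in range(10)],
        )
        truth = {f"C{i}": classes[i] for i in range(10)}
        rep = evaluate_moa(df, truth, classes + ["DMSO"])
        assert rep.accuracy == pytest.approx(0.1)

    def test_three_class_confusion_matches_brute_force(self):
        y_true = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        y_pred = ["a", "a", "b", "c", "a", "b", "b", "a", "c", "c"]
        df = pd.DataFrame(
            {"label": y_pred, "top3": [[p] for p in y_pred]},
            index=[f"C{i}" for i in range(10)],
        )
        rep = evaluate_moa(df, dict(zip(df.index, y_true)), ["a", "b", "c"])
        # brute-force per-class F1 and support-weighted mean
        f1s, supports = {}, {}
        for cls in ("a", "b", "c"):
            tp = sum(t == p == cls for t, p in zip(y_true, y_pred))
            fp = sum(p == cls and t != cls for t, p in zip(y_true, y_pred))
            fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s[cls] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            supports[cls] = y_true.count(cls)
        expected_f1w = sum(f1s[c] * supports[c] for c in f1s) / len(y_true)
        assert rep.f1_weighted == pytest.approx(expected_f1w, abs=1e-12)
        assert (rep.confusion_matrix.sum(axis=1).to_numpy() == [5, 3, 2]).all()

    def test_unknown_prediction_label_rejected(self):
        df = pd.DataFrame({"label": ["zzz"], "top3": [["zzz"]]}, index=["C1"])
        with pytest.raises(ValueError, match="outside the class set"):
            evaluate_moa(df, {"C1": "a"}, ["a", "b"])


class TestFolds:
    def _compounds(self, n_moa=4, per=5):
        return pd.DataFrame(
            {
                "compound": [f"C{m}_{i}" for m in range(n_moa) for i in range(per)],
                "moa": [f"m{m}" for m in range(n_moa) for i in range(per)],
            }
        )

    def test_partition_property(self):
        comp = self._compounds()
        folds = assign_folds(comp, k=5, seed=0)
        assert set(folds) == set(comp["compound"])
        counts = pd.Series(list(folds.values())).value_counts()
        assert counts.sum() == len(comp)
        # stratified: each MoA's 5 compounds land in 5 distinct folds
        df = comp.assign(fold=comp["compound"].map(folds))
        assert (df.groupby("moa")["fold"].nunique() == 5).all()

    def test_deterministic(self):
        comp = self._compounds()
        assert assign_folds(comp, 5, seed=1) == assign_folds(comp, 5, seed=1)

    def test_small_class_warns(self):
        comp = self._compounds(per=2)
        with pytest.warns(UserWarning, match="best-effort"):
            assign_folds(comp, k=5, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(self._compounds(), k=1, seed=0)


class TestCrossValidate:
    def test_every_compound_predicted_once_per_condition(self, moa_dataset):
        wells, calls, truth = moa_dataset
        with pytest.warns(UserWarning, match="best-effort"):
            preds, classes = cross_validate(wells, activity_calls=calls, k=5, seed=7)
        n_compounds = truth.compounds.shape[0]
        for p in preds:
            # out-of-fold rows: each compound appears exactly once
            assert p.probabilities.index.is_unique
            assert len(p.probabilities) == n_compounds
        assert "DMSO" in classes


class TestMcNemar:
    def _series(self, vals):
        return pd.Series(vals, index=[f"C{i}" for i in range(len(vals))])

    def test_identical_predictions(self):
        a = self._series(["x", "y", "x"])
        truth = {"C0": "x", "C1": "x", "C2": "x"}
        assert mcnemar_test(a, a.copy(), truth) == (0.0, 1.0)

    def test_hand_statistic_b10_c0(self):
        truth = {f"C{i}": "x" for i in range(12)}
        a = self._series(["x"] * 10 + ["y", "y"])  # 10 right, 2 wrong
        b = self._series(["y"] * 10 + ["y", "y"])  # those 10 wrong, same 2 wrong
        stat, p = mcnemar_test(a, b, truth)
        assert stat == pytest.approx(10.0)

    def test_exact_small_sample_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        truth = {f"C{i}": "x" for i in range(10)}
        # b = 4 (a right, b wrong), c = 2 (a wrong, b right), 4 both right
        a = self._series(["x", "x", "x", "x", "y", "y", "x", "x", "x", "x"])
        b = self._series(["y", "y", "y", "y", "x", "x", "x", "x", "x", "x"])
        stat, p = mcnemar_test(a, b, truth)
        table = [[0, 4], [2, 0]]  # only discordant cells matter
        expected = sm_mcnemar(table, exact=True)
        assert p == pytest.approx(float(expected.pvalue), abs=1e-12)

    def test_large_sample_chi2_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        n = 60
        truth = {f"C{i}": "x" for i in range(n)}
        a_vals = ["x"] * 20 + ["y"] * 10 + ["x"] * 30
        b_vals = ["y"] * 20 + ["x"] * 10 + ["x"] * 30
        stat, p = mcnemar_test(self._series(a_vals), self._series(b_vals), truth)
        expected = sm_mcnemar([[30, 20], [10, 0]], exact=False, correction=False)
        assert stat == pytest.approx(float(expected.statistic))
        assert p == pytest.approx(float(expected.pvalue), abs=1e-12)
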