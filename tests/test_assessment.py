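"""Metrics, assessors, grid search and plot-ready summaries, with an
independent hand-rolled cross-validation oracle."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

import qsarkit as qk
from qsarkit.assessment import AGGREGATORS, r2_score, rmse, summarize
from qsarkit.filters import FeatureStandardizer, LowVarianceFilter
from qsarkit.persistence import derive_seed
from qsarkit.synth import FixtureSpec, make_dataframe, make_dataset
from qsarkit.tasks import TargetProperty, TargetTask


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_score(y, y) == 1.0
        assert rmse(y, y) == 0.0

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_score(y, np.full(3, 2.0)) == 0.0

    def test_anticorrelated_hand_value(self):
        # SS_res = 2, SS_tot = 0.5 -> r2 = 1 - 4 = -3
        assert r2_score([0, 1], [1, 0]) == -3.0

    def test_zero_variance_truth_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            r2_score([2.0, 2.0], [1.0, 3.0])


@pytest.fixture(scope="module")
def fifty_row_dataset():
    ds = make_dataset(FixtureSpec(n_molecules=50))
    ds.prepare(descriptor_sets=[qk.MorganFingerprint()],
               splitter=qk.RandomSplit(0.2),
               feature_filters=[qk.LowVarianceFilter(0.0)],
               standardize=True)
    return ds


def hand_rolled_cv(ds, n_folds, seed, n_neighbors=3):
    """Independent loop: same folds, fold-internal pipeline, sklearn
    estimator called directly."""
    train = ds.subset_indices("train")
    raw = ds.descriptor_matrix()
    y = ds.table["pchembl"].to_numpy()
    scores = []
    for tr, va in KFold(n_folds, shuffle=True,
                        random_state=seed).split(np.zeros(len(train))):
        tr_rows, va_rows = train[tr], train[va]
        med = raw.iloc[tr_rows].median(axis=0)
        work = raw.fillna(med)
        lv = LowVarianceFilter(0.0).fit(work.iloc[tr_rows])
        cols = lv.selected_
        std = FeatureStandardizer().fit(work.iloc[tr_rows][cols])
        est = KNeighborsRegressor(n_neighbors=n_neighbors)
        est.fit(std.transform(work.iloc[tr_rows][cols]).to_numpy(),
                y[tr_rows])
        pred = est.predict(std.transform(work.iloc[va_rows][cols]).to_numpy())
        scores.append(r2_score(y[va_rows], pred))
    return scores


class TestCrossValAssessor:
    def test_matches_hand_rolled_oracle(self, fifty_row_dataset, tmp_path):
        ds = fifty_row_dataset
        seed = 11
        model = qk.SklearnModel("knn", "KNeighborsRegressor",
                                {"n_neighbors": 3})
        res = qk.CrossValAssessor(5, "r2", seed=seed, model_dir=tmp_path)(
            model, ds)
        expected = hand_rolled_cv(ds, 5, seed)
        np.testing.assert_allclose(res.scores, expected, atol=1e-12)

    def test_every_training_row_predicted_once(self, fifty_row_dataset,
                                               tmp_path):
        model = qk.SklearnModel("knn", "KNeighborsRegressor",
                                {"n_neighbors": 3})
        res = qk.CrossValAssessor(5, "r2", seed=1, model_dir=tmp_path)(
            model, fifty_row_dataset)
        assert len(res.scores) == 5
        train_ids = [fifty_row_dataset.ids[i]
                     for i in fifty_row_dataset.subset_indices("train")]
        assert sorted(res.predictions["mol_id"]) == sorted(train_ids)

    def test_bitwise_reproducible(self, fifty_row_dataset):
        model = qk.SklearnModel("knn", "KNeighborsRegressor",
                                {"n_neighbors": 3})
        a = qk.CrossValAssessor(5, "r2", seed=2)(model, fifty_row_dataset)
        b = qk.CrossValAssessor(5, "r2", seed=2)(model, fifty_row_dataset)
        assert a.scores == b.scores

    def test_scores_recomputable_from_predictions(self, fifty_row_dataset):
        model = qk.SklearnModel("knn", "KNeighborsRegressor",
                                {"n_neighbors": 3})
        res = qk.CrossValAssessor(5, "r2", seed=3)(model, fifty_row_dataset)
        for fold, score in enumerate(res.scores):
            rec = res.predictions[res.predictions["Fold"] == fold]
            recomputed = r2_score(rec["pchembl_Label"],
                                  rec["pchembl_Prediction"])
            assert abs(recomputed - score) < 1e-12

    def test_single_class_fold_errors(self):
        df = pd.DataFrame({"smiles": ["CCO", "CCC", "CCCC", "CCN", "CCCN",
                                      "CCCCN"],
                           "y": [0.0, 0.0, 0.0, 0.0, 0.0, 9.0]})
        ds = qk.QSARDataset.from_table(
            df, "smiles", [TargetProperty("y", TargetTask.SINGLECLASS,
                                          [5.0])])
        ds.prepare(descriptor_sets=[qk.MorganFingerprint(2, 256)],
                   splitter=qk.ManualSplit(["train"] * 5 + ["test"]))
        model = qk.SklearnModel("knnc", "KNeighborsClassifier",
                                {"n_neighbors": 1})
        with pytest.raises(ValueError, match="single class"):
            qk.CrossValAssessor(5, "balanced_accuracy", seed=0)(model, ds)


class TestLeakageGuard:
    def test_leaky_feature_does_not_inflate_cv_score(self):
        """A feature equal to y on what will become each fold's held-out
        rows cannot leak through fold-internal refitting."""
        spec = FixtureSpec(n_molecules=50)
        df, _ = make_dataframe(spec)
        base = qk.QSARDataset.from_table(
            df, "smiles",
            [TargetProperty("pchembl", TargetTask.REGRESSION)],
            random_state=7)
        y = base.table["pchembl"].to_numpy()
        rng = np.random.default_rng(7)
        # leak detector: y itself plus tiny jitter, as an extra descriptor
        leak = pd.DataFrame({"mol_id": base.ids,
                             "leak": y + rng.normal(0, 1e-9, len(y))})
        model = qk.SklearnModel("knn", "KNeighborsRegressor",
                                {"n_neighbors": 3})

        def cv_mean(with_leak):
            ds = qk.QSARDataset.from_table(
                df, "smiles",
                [TargetProperty("pchembl", TargetTask.REGRESSION)],
                random_state=7)
            dsets = [qk.MorganFingerprint()]
            if with_leak:
                dsets.append(qk.TabularDescriptors(leak, "mol_id"))
            ds.prepare(descriptor_sets=dsets, splitter=qk.RandomSplit(0.2),
                       feature_filters=[qk.LowVarianceFilter(0.0)],
                       standardize=True)
            if with_leak:
                # hide the leak from fold-train rows: replace by the median
                # everywhere except the rows a fold will hold out is not
                # expressible ahead of the folds, so instead the leak column
                # is NaN on training rows and real only on test rows
                train = ds.subset_indices("train")
                col = ds.descriptors[dsets[1].name].columns[0]
                ds.descriptors[dsets[1].name].iloc[
                    train, 0] = np.nan
            res = qk.CrossValAssessor(5, "r2", seed=4)(model, ds)
            return float(np.mean(res.scores))

        baseline = cv_mean(False)
        leaked = cv_mean(True)
        assert leaked <= baseline + 0.05


class TestTestSetAssessor:
    def test_memorizing_model_perfect_on_duplicated_test(self):
        smiles = ["CCO", "CCC", "CCCC", "CCN", "CCCN"]
        df = pd.DataFrame({"smiles": smiles + smiles[:2],
                           "y": [1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 2.0]})
        ds = qk.QSARDataset.from_table(
            df, "smiles", [TargetProperty("y", TargetTask.REGRESSION)])
        ds.prepare(descriptor_sets=[qk.MorganFingerprint(2, 512)],
                   splitter=qk.ManualSplit(["train"] * 5 + ["test"] * 2))
        model = qk.SklearnModel("knn1", "KNeighborsRegressor",
                                {"n_neighbors": 1})
        model.fit(ds)
        res = qk.TestSetAssessor("r2")(model, ds)
        assert res.scores[0] == pytest.approx(1.0)

    def test_tsv_row_count_equals_test_size(self, fifty_row_dataset,
                                            tmp_path, ):
        model = qk.SklearnModel("knn", "KNeighborsRegressor",
                                {"n_neighbors": 3})
        model.fit(fifty_row_dataset)
        qk.TestSetAssessor("r2", model_dir=tmp_path)(model,
                                                     fifty_row_dataset)
        rec = pd.read_csv(tmp_path / "test_predictions.tsv", sep="\t")
        assert len(rec) == len(fifty_row_dataset.subset_indices("test"))

    def test_baseline_near_zero_on_shuffled_labels(self):
        rng = np.random.default_rng(0)
        df, _ = make_dataframe(FixtureSpec(n_molecules=50))
        df["pchembl"] = rng.permutation(df["pchembl"].to_numpy())
        ds = qk.QSARDataset.from_table(
            df, "smiles",
            [TargetProperty("pchembl", TargetTask.REGRESSION)],
            random_state=0)
        ds.prepare(descriptor_sets=[qk.MorganFingerprint()],
                   splitter=qk.RandomSplit(0.2))
        model = qk.MedianBaseline()
        model.fit(ds)
        assert qk.TestSetAssessor("r2")(model, ds).scores[0] <= 0.05


class TestGridSearch:
    def test_product_size_and_argmax_consistency(self, fifty_row_dataset):
        model = qk.SklearnModel("knn", "KNeighborsRegressor")
        gs = qk.GridSearch({"n_neighbors": [1, 3], "weights":
                            ["uniform", "distance"]},
                           qk.CrossValAssessor(3, "r2", seed=5))
        best, table = gs.optimize(model, fifty_row_dataset)
        assert len(table) == 4
        assert table["score"].max() == table.set_index(
            ["n_neighbors", "weights"]).loc[
            (best["n_neighbors"], best["weights"]), "score"]

    def test_planted_optimum_selected(self, fifty_row_dataset):
        # an absurdly large ridge penalty forces near-constant predictions,
        # so the small penalty must win; both scores checked explicitly
        model = qk.SklearnModel("ridge", "Ridge")
        gs = qk.GridSearch({"alpha": [0.1, 1e9]},
                           qk.CrossValAssessor(3, "r2", seed=5))
        best, table = gs.optimize(model, fifty_row_dataset)
        s_small = table.loc[table["alpha"] == 0.1, "score"].iloc[0]
        s_big = table.loc[table["alpha"] == 1e9, "score"].iloc[0]
        assert s_small > s_big
        assert best == {"alpha": 0.1}

    def test_order_invariance_up_to_ties(self, fifty_row_dataset):
        model = qk.SklearnModel("knn", "KNeighborsRegressor")
        a, _ = qk.GridSearch({"n_neighbors": [1, 5, 9]},
                             qk.CrossValAssessor(3, "r2", seed=5)).optimize(
            model, fifty_row_dataset)
        b, _ = qk.GridSearch({"n_neighbors": [9, 5, 1]},
                             qk.CrossValAssessor(3, "r2", seed=5)).optimize(
            model, fifty_row_dataset)
        assert a == b

    def test_empty_value_list_errors(self):
        with pytest.raises(ValueError, match="empty value list"):
            qk.GridSearch({"k": []}, None)

    def test_aggregators_available(self):
        assert set(AGGREGATORS) == {"mean", "median", "min"}


class TestSummaries:
    def make_classifier_outputs(self, tmp_path, perfect):
        rng = np.random.default_rng(8)
        n = 2000
        y = rng.integers(0, 2, n)
        proba1 = y.astype(float) if perfect else rng.random(n)
        rec = pd.DataFrame({
            "mol_id": [f"m_{i}" for i in range(n)],
            "Fold": "Independent Test",
            "y_Label": y,
            "y_Prediction": (proba1 > 0.5).astype(int),
            "y_ProbabilityClass_0": 1 - proba1,
            "y_ProbabilityClass_1": proba1,
        })
        rec.to_csv(tmp_path / "test_predictions.tsv", sep="\t", index=False)
        return [TargetProperty("y", TargetTask.SINGLECLASS, [0.5])]

    def test_perfect_classifier_roc(self, tmp_path):
        tps = self.make_classifier_outputs(tmp_path, perfect=True)
        tables = summarize(tmp_path, tps)
        roc = tables["y_roc"]
        cls1 = roc[roc["class"] == 1]
        assert ((cls1["fpr"] == 0) & (cls1["tpr"] == 1)).any()
        metrics = tables["y_class_metrics"]
        assert metrics.loc[metrics["class"] == 1, "auc"].iloc[0] == 1.0

    def test_random_probabilities_auc_near_half(self, tmp_path):
        tps = self.make_classifier_outputs(tmp_path, perfect=False)
        tables = summarize(tmp_path, tps)
        metrics = tables["y_class_metrics"]
        auc = metrics.loc[metrics["class"] == 1, "auc"].iloc[0]
        assert 0.45 <= auc <= 0.55

    def test_calibration_bins_partition_unit_interval(self, tmp_path):
        tps = self.make_classifier_outputs(tmp_path, perfect=False)
        cal = summarize(tmp_path, tps)["y_calibration"]
        assert cal["count"].sum() == 2000
        assert cal["bin_lower"].iloc[0] == 0.0
        assert cal["bin_upper"].iloc[-1] == 1.0

    def test_missing_tsv_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="test_predictions.tsv"):
            summarize(tmp_path, [])

    def test_regression_stats_match_metrics(self, tmp_path,
                                            fifty_row_dataset):
        model = qk.SklearnModel("knn", "KNeighborsRegressor",
                                {"n_neighbors": 3})
        model.fit(fifty_row_dataset)
        res = qk.TestSetAssessor("r2", model_dir=tmp_path)(
            model, fifty_row_dataset)
        tables = summarize(tmp_path, fifty_row_dataset.target_properties)
        assert tables["pchembl_stats"]["r2"].iloc[0] == pytest.approx(
            res.scores[0], abs=1e-12)


def test_derive_seed_distinct_labels():
    assert derive_seed(42, "replica_0") != derive_seed(42, "replica_1")
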