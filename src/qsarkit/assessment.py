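"""Metrics, cross-validation and test-set assessment, grid search, and
plot-ready result summaries.

Cross-validation deliberately repeats feature filtering and
standardization inside every fold, fitted on the fold-train rows only,
so no information from held-out rows can leak into the feature pipeline.
Both assessors write per-row prediction TSVs to the model directory;
every reported score is recomputable from those records.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import KFold, StratifiedKFold

from .data import ID_COL, QSARDataset
from .filters import FeatureStandardizer, feature_filter_from_config
from .persistence import derive_seed

TEST_FOLD_LABEL = "Independent Test"


# ---------------------------------------------------------------------------
# Metrics

def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about the mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 2:
        raise ValueError("r2 needs at least two rows")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("r2 undefined: y_true has zero variance")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _roc_auc(y_true, proba) -> float:
    proba = np.asarray(proba)
    if proba.ndim == 2 and proba.shape[1] == 2:
        proba = proba[:, 1]
    if proba.ndim == 2:
        return float(skm.roc_auc_score(y_true, proba, multi_class="ovr"))
    return float(skm.roc_auc_score(y_true, proba))


@dataclass(frozen=True)
class Metric:
    """A named scoring function with an optimization direction."""

    name: str
    func: Callable
    direction: str = "maximize"  # or "minimize"
    needs_proba: bool = False

    def __call__(self, y_true, y_pred) -> float:
        return float(self.func(y_true, y_pred))


METRICS = {
    "r2": Metric("r2", r2_score),
    "rmse": Metric("rmse", rmse, direction="minimize"),
    "balanced_accuracy": Metric("balanced_accuracy", skm.balanced_accuracy_score),
    "mcc": Metric("mcc", skm.matthews_corrcoef),
    "roc_auc": Metric("roc_auc", _roc_auc, needs_proba=True),
}

AGGREGATORS = {"mean": np.mean, "median": np.median, "min": np.min}


@dataclass
class AssessmentResult:
    """Per-fold (or single test) scores plus traceable prediction records."""

    scores: list[float]
    predictions: pd.DataFrame
    per_task: pd.DataFrame = field(default_factory=pd.DataFrame)

    def aggregate(self, aggregator: str = "mean") -> float:
        return float(AGGREGATORS[aggregator](self.scores))


# ---------------------------------------------------------------------------
# Helpers

def _prediction_frame(dataset, rows: np.ndarray, fold_label, model,
                      X: np.ndarray) -> pd.DataFrame:
    rec = pd.DataFrame({ID_COL: dataset.table[ID_COL].iloc[rows].to_numpy(),
                        "Fold": fold_label})
    preds = model.predict(X)
    probas = model.predict_proba(X) if any(
        tp.task.is_classification for tp in dataset.target_properties) else []
    pi = 0
    for j, tp in enumerate(dataset.target_properties):
        rec[f"{tp.name}_Label"] = dataset.table[tp.label_column].iloc[
            rows].to_numpy()
        rec[f"{tp.name}_Prediction"] = preds[:, j]
        if tp.task.is_classification:
            for k in range(tp.n_classes):
                rec[f"{tp.name}_ProbabilityClass_{k}"] = probas[pi][:, k]
            pi += 1
    return rec


def _score_tasks(dataset, rec: pd.DataFrame, metric: Metric) -> dict[str, float]:
    out = {}
    for tp in dataset.target_properties:
        y_true = rec[f"{tp.name}_Label"].to_numpy(dtype=float)
        if metric.needs_proba and tp.task.is_classification:
            cols = [f"{tp.name}_ProbabilityClass_{k}"
                    for k in range(tp.n_classes)]
            y_pred = rec[cols].to_numpy(dtype=float)
        else:
            y_pred = rec[f"{tp.name}_Prediction"].to_numpy(dtype=float)
        mask = ~np.isnan(y_true)
        out[tp.name] = metric(y_true[mask],
                              y_pred[mask] if y_pred.ndim == 1 else y_pred[mask])
    return out


def _write_tsv(frame: pd.DataFrame, model_dir, filename: str) -> None:
    if model_dir is None:
        return
    path = Path(model_dir)
    path.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path / filename, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Assessors

class TestSetAssessor:
    """Score a fitted model on the dataset's held-out test subset."""

    def __init__(self, metric: Metric | str = "r2",
                 model_dir: str | Path | None = None):
        self.metric = METRICS[metric] if isinstance(metric, str) else metric
        self.model_dir = model_dir

    def __call__(self, model, dataset: QSARDataset) -> AssessmentResult:
        test = dataset.subset_indices("test")
        if len(test) == 0:
            raise ValueError("dataset has no test subset")
        X = dataset.get_features("test").to_numpy(dtype=float)
        rec = _prediction_frame(dataset, test, TEST_FOLD_LABEL, model, X)
        per_task = _score_tasks(dataset, rec, self.metric)
        _write_tsv(rec, self.model_dir, "test_predictions.tsv")
        score = float(np.mean(list(per_task.values())))
        return AssessmentResult([score], rec,
                                pd.DataFrame([per_task]))


class CrossValAssessor:
    """k-fold cross-validation on the training subset.

    Each fold refits the feature filters and standardizer on its own
    fold-train rows (leakage-safe), fits a fresh model clone and scores
    the held-out fold; one score per fold is returned.
    """

    def __init__(self, n_folds: int = 5, metric: Metric | str = "r2",
                 seed: int | None = None,
                 model_dir: str | Path | None = None):
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        self.n_folds = n_folds
        self.metric = METRICS[metric] if isinstance(metric, str) else metric
        self.seed = seed
        self.model_dir = model_dir

    def _fold_pipeline(self, dataset, raw: pd.DataFrame, fold_train_rows):
        """Fit filters + imputation + standardizer on fold-train rows only."""
        medians = raw.iloc[fold_train_rows].median(axis=0)
        work = raw.fillna(medians)
        cols = list(raw.columns)
        for cfg in dataset.recipe.get("feature_filters", []):
            ff = feature_filter_from_config({**cfg, "selected": None})
            ff.fit(work.iloc[fold_train_rows][cols])
            cols = list(ff.selected_)
        std = None
        if dataset.standardizer is not None:
            std = FeatureStandardizer().fit(
                work.iloc[fold_train_rows][cols])
        def transform(rows):
            sub = work.iloc[rows][cols]
            return (std.transform(sub) if std is not None else sub).to_numpy(
                dtype=float)
        return transform

    def __call__(self, model, dataset: QSARDataset) -> AssessmentResult:
        train = dataset.subset_indices("train")
        raw = dataset.descriptor_matrix()
        y_all = dataset.get_targets("all")
        seed = self.seed if self.seed is not None else derive_seed(
            dataset.random_state, "cv")
        single_clf = (len(dataset.target_properties) == 1 and
                      dataset.target_properties[0].task.is_classification)
        if single_clf:
            labels = y_all.iloc[train, 0].to_numpy()
            splitter = StratifiedKFold(self.n_folds, shuffle=True,
                                       random_state=seed)
            folds = splitter.split(np.zeros(len(train)), labels)
        else:
            splitter = KFold(self.n_folds, shuffle=True, random_state=seed)
            folds = splitter.split(np.zeros(len(train)))
        scores, records, per_task_rows = [], [], []
        for fold_id, (tr, va) in enumerate(folds):
            tr_rows, va_rows = train[tr], train[va]
            for tp in dataset.target_properties:
                if tp.task.is_classification:
                    classes = set(y_all[tp.label_column].iloc[tr_rows].dropna())
                    if len(classes) < 2:
                        raise ValueError(
                            f"fold {fold_id} has a single class for "
                            f"{tp.name!r}")
            transform = self._fold_pipeline(dataset, raw, tr_rows)
            clone = model.clone()
            clone.task = dataset.task
            clone.target_properties = list(dataset.target_properties)
            if clone.random_state is None:
                clone.random_state = dataset.random_state
            clone._fit_arrays(transform(tr_rows),
                              y_all.iloc[tr_rows])
            clone.is_fitted = True
            rec = _prediction_frame(dataset, va_rows, fold_id, clone,
                                    transform(va_rows))
            per_task = _score_tasks(dataset, rec, self.metric)
            per_task_rows.append(per_task)
            scores.append(float(np.mean(list(per_task.values()))))
            records.append(rec)
        all_rec = pd.concat(records, ignore_index=True)
        _write_tsv(all_rec, self.model_dir, "cv_predictions.tsv")
        return AssessmentResult(scores, all_rec, pd.DataFrame(per_task_rows))


# ---------------------------------------------------------------------------
# Hyperparameter optimization

class HyperparameterOptimization:
    """Shared contract: a search space, an assessor and an aggregator."""

    def __init__(self, search_space: dict[str, Sequence], assessor,
                 aggregator: str = "mean"):
        if not search_space:
            raise ValueError("search space is empty")
        for k, v in search_space.items():
            if not len(v):
                raise ValueError(f"empty value list for parameter {k!r}")
        self.search_space = {k: list(v) for k, v in search_space.items()}
        self.assessor = assessor
        self.aggregator = aggregator

    def optimize(self, model_template, dataset):  # pragma: no cover - abstract
        raise NotImplementedError


class GridSearch(HyperparameterOptimization):
    """Exhaustive evaluation of the Cartesian product of the search space.

    Returns the best parameters (first-in-product-order on ties) and a
    score table recording every combination.
    """

    def optimize(self, model_template, dataset,
                 model_dir: str | Path | None = None):
        keys = list(self.search_space)
        rows = []
        best_params, best_score = None, None
        maximize = self.assessor.metric.direction == "maximize"
        for combo in itertools.product(*(self.search_space[k] for k in keys)):
            params = dict(zip(keys, combo))
            candidate = model_template.clone()
            candidate.params = {**candidate.params, **params}
            result = self.assessor(candidate, dataset)
            agg = result.aggregate(self.aggregator)
            rows.append({**params, "score": agg})
            better = (best_score is None or
                      (agg > best_score if maximize else agg < best_score))
            if better:
                best_params, best_score = params, agg
        table = pd.DataFrame(rows)
        _write_tsv(table, model_dir, "score_table.tsv")
        return best_params, table


# ---------------------------------------------------------------------------
# Plot-ready summaries

def _calibration_bins(y_true: np.ndarray, proba: np.ndarray,
                      n_bins: int = 10) -> pd.DataFrame:
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(proba, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        rows.append({"bin_lower": edges[b], "bin_upper": edges[b + 1],
                     "count": int(mask.sum()),
                     "mean_predicted": float(proba[mask].mean()) if mask.any()
                     else math.nan,
                     "fraction_positive": float(y_true[mask].mean())
                     if mask.any() else math.nan})
    return pd.DataFrame(rows)


def summarize(model_dir: str | Path, target_properties,
              source: str = "test") -> dict[str, pd.DataFrame]:
    """Numeric tables sufficient to draw assessment plots.

    For classifiers: ROC points, calibration bins and one-vs-rest
    per-class metrics with macro and weighted averages. For regression:
    a scatter table (id, label, prediction) plus summary statistics.
    """
    path = Path(model_dir) / f"{source}_predictions.tsv"
    if not path.exists():
        raise FileNotFoundError(f"expected predictions at {path}")
    rec = pd.read_csv(path, sep="\t")
    out: dict[str, pd.DataFrame] = {}
    for tp in target_properties:
        y_true = rec[f"{tp.name}_Label"].to_numpy(dtype=float)
        if tp.task.is_classification:
            n_classes = tp.n_classes
            proba = rec[[f"{tp.name}_ProbabilityClass_{k}"
                         for k in range(n_classes)]].to_numpy(dtype=float)
            roc_rows, cls_rows = [], []
            for k in range(n_classes):
                binary = (y_true == k).astype(int)
                fpr, tpr, thr = skm.roc_curve(binary, proba[:, k])
                roc_rows.append(pd.DataFrame(
                    {"class": k, "fpr": fpr, "tpr": tpr, "threshold": thr}))
                pred_k = (rec[f"{tp.name}_Prediction"] == k).astype(int)
                cls_rows.append({
                    "class": k,
                    "auc": float(skm.roc_auc_score(binary, proba[:, k])),
                    "precision": float(skm.precision_score(
                        binary, pred_k, zero_division=0)),
                    "recall": float(skm.recall_score(
                        binary, pred_k, zero_division=0)),
                    "support": int(binary.sum()),
                })
            per_class = pd.DataFrame(cls_rows)
            weights = (per_class["support"]
                       / per_class["support"].sum()).to_numpy()
            avg_rows = []
            for avg, w in (("macro", None), ("weighted", weights)):
                row = {"class": avg,
                       "support": int(per_class["support"].sum())}
                for col in ("auc", "precision", "recall"):
                    row[col] = float(np.average(per_class[col].to_numpy(),
                                                weights=w))
                avg_rows.append(row)
            cls_table = pd.concat([per_class, pd.DataFrame(avg_rows)],
                                  ignore_index=True)
            out[f"{tp.name}_roc"] = pd.concat(roc_rows, ignore_index=True)
            out[f"{tp.name}_calibration"] = _calibration_bins(
                (y_true == (n_classes - 1)).astype(float),
                proba[:, n_classes - 1])
            out[f"{tp.name}_class_metrics"] = cls_table
        else:
            y_pred = rec[f"{tp.name}_Prediction"].to_numpy(dtype=float)
            out[f"{tp.name}_scatter"] = rec[
                [ID_COL, f"{tp.name}_Label", f"{tp.name}_Prediction"]].copy()
            out[f"{tp.name}_stats"] = pd.DataFrame([{
                "r2": r2_score(y_true, y_pred),
                "rmse": rmse(y_true, y_pred),
                "n": len(y_true)}])
    return out
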