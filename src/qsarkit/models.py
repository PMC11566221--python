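"""Model abstraction: estimator wrapper, baseline, PCM variant and
deployment-time prediction from SMILES.

A :class:`QSARModel` couples an estimator with the complete featurization
recipe captured from the prepared dataset at fit time, so a raw SMILES
(plus a protein id for PCM) is all that is needed to predict. Models are
serializable as a directory of JSON metadata plus estimator payloads and
predict identically after a save/load round trip.

Estimators without native multi-task support are lifted by fitting one
estimator per task; this composition is recorded in the metadata.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn import ensemble, linear_model, neighbors, svm, tree

from . import persistence
from .data import PCMDataset, QSARDataset
from .descriptors import descriptor_from_config
from .domain import ApplicabilityDomain, ad_from_config
from .filters import FeatureStandardizer
from .tasks import ModelTask, TargetProperty, infer_task

ALGORITHMS = {
    "KNeighborsRegressor": neighbors.KNeighborsRegressor,
    "KNeighborsClassifier": neighbors.KNeighborsClassifier,
    "RandomForestRegressor": ensemble.RandomForestRegressor,
    "RandomForestClassifier": ensemble.RandomForestClassifier,
    "ExtraTreesRegressor": ensemble.ExtraTreesRegressor,
    "GradientBoostingRegressor": ensemble.GradientBoostingRegressor,
    "Ridge": linear_model.Ridge,
    "LogisticRegression": linear_model.LogisticRegression,
    "SVR": svm.SVR,
    "SVC": svm.SVC,
    "DecisionTreeRegressor": tree.DecisionTreeRegressor,
    "DecisionTreeClassifier": tree.DecisionTreeClassifier,
}
try:  # optional gradient boosting backend
    import xgboost

    ALGORITHMS["XGBRegressor"] = xgboost.XGBRegressor
    ALGORITHMS["XGBClassifier"] = xgboost.XGBClassifier
except ImportError:  # pragma: no cover
    pass


class QSARModel:
    """Task-aware model wrapping an estimator plus its preparation recipe."""

    def __init__(self, name: str, random_state: int | None = None):
        self.name = name
        self.random_state = random_state
        self.task: ModelTask | None = None
        self.target_properties: list[TargetProperty] = []
        self.is_fitted = False
        self.estimators_: list = []
        self.descriptor_sets: list = []
        self.protein_descriptor_sets: list = []
        self.protein_sequences: dict[str, str] = {}
        self.feature_names: list[str] | None = None
        self.imputation: dict[str, float] = {}
        self.standardizer: FeatureStandardizer | None = None
        self.y_imputation: dict[str, float] = {}
        self.applicability_domain: ApplicabilityDomain | None = None
        self.metadata: dict = {}
        self._payload_bytes: list[bytes] | None = None

    # -- estimator hooks (overridden by subclasses) ------------------------
    def _make_estimator(self):
        raise NotImplementedError

    def estimator_spec(self) -> dict:
        return {"class": type(self).__name__}

    def clone(self) -> "QSARModel":
        out = copy.copy(self)
        out.is_fitted = False
        out.estimators_ = []
        out._payload_bytes = None
        return out

    # -- fitting -----------------------------------------------------------
    def fit(self, dataset: QSARDataset) -> "QSARModel":
        task = dataset.task
        if self.task is not None and self.task != task:
            raise ValueError(
                f"model task {self.task} incompatible with dataset task {task}")
        self.task = task
        self.target_properties = list(dataset.target_properties)
        if self.random_state is None:
            self.random_state = dataset.random_state
        X = dataset.get_features("train").to_numpy(dtype=float)
        y = dataset.get_targets("train")
        if len(X) == 0:
            raise ValueError("empty training set")
        self._capture_recipe(dataset)
        self._fit_arrays(X, y)
        self.metadata.update({
            "n_train": int(len(X)),
            "n_features": int(X.shape[1]),
            "seed": self.random_state,
            "task": self.task.value,
            "multitask_lift": "one_estimator_per_task",
            "y_imputation": self.y_imputation,
        })
        if self.applicability_domain is not None and \
                not self.applicability_domain.is_fitted:
            # model-level AD is fitted on the whole prepared dataset
            self.applicability_domain.fit(
                dataset.get_features("all").to_numpy(dtype=float))
        self.is_fitted = True
        self._payload_bytes = None
        return self

    def _capture_recipe(self, dataset: QSARDataset) -> None:
        self.descriptor_sets = list(dataset.descriptor_sets)
        self.feature_names = list(dataset.feature_names or [])
        self.imputation = dict(dataset.imputation)
        self.standardizer = dataset.standardizer
        if isinstance(dataset, PCMDataset):
            self.protein_descriptor_sets = list(dataset.protein_descriptor_sets)
            self.protein_sequences = dict(dataset.protein_sequences)
            self.protein_id_column = dataset.protein_id_column

    def _fit_arrays(self, X: np.ndarray, y: pd.DataFrame) -> None:
        """Fit one estimator per task; missing labels are imputed with
        the per-task training median (recorded in metadata)."""
        self.estimators_ = []
        self.y_imputation = {}
        for col in y.columns:
            yi = y[col].to_numpy(dtype=float)
            if np.isnan(yi).any():
                med = float(np.nanmedian(yi))
                self.y_imputation[col] = med
                yi = np.where(np.isnan(yi), med, yi)
            est = self._make_estimator()
            tp = next(t for t in self.target_properties if t.label_column == col)
            if tp.task.is_classification:
                yi = yi.astype(int)
            est.fit(X, yi)
            self.estimators_.append(est)

    # -- prediction --------------------------------------------------------
    @property
    def output_columns(self) -> list[str]:
        """Prediction (regression) and per-class probability columns."""
        cols = []
        for tp in self.target_properties:
            if tp.task.is_classification:
                cols.extend(f"{tp.name}_ProbabilityClass_{k}"
                            for k in range(tp.n_classes))
            else:
                cols.append(f"{tp.name}_Prediction")
        return cols

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Point predictions, one column per task; classifier argmax ties
        resolve to the lowest class index."""
        if not self.is_fitted:
            raise RuntimeError(f"model {self.name!r} is not fitted")
        X = np.asarray(X, dtype=float)
        cols = []
        for tp, est in zip(self.target_properties, self.estimators_):
            if tp.task.is_classification and hasattr(est, "predict_proba"):
                proba = est.predict_proba(X)
                labels = np.asarray(est.classes_)[np.argmax(proba, axis=1)]
                cols.append(labels.astype(float))
            else:
                cols.append(np.asarray(est.predict(X), dtype=float))
        return np.column_stack(cols)

    def predict_proba(self, X: np.ndarray) -> list[np.ndarray]:
        """Per-task class-probability matrices (classification tasks only)."""
        if not self.is_fitted:
            raise RuntimeError(f"model {self.name!r} is not fitted")
        out = []
        for tp, est in zip(self.target_properties, self.estimators_):
            if not tp.task.is_classification:
                continue
            proba = est.predict_proba(np.asarray(X, dtype=float))
            full = np.zeros((len(proba), tp.n_classes))
            for j, cls in enumerate(est.classes_):
                full[:, int(cls)] = proba[:, j]
            out.append(full)
        return out

    # -- featurization replay ---------------------------------------------
    @property
    def is_pcm(self) -> bool:
        return bool(self.protein_sequences)

    def featurize(self, smiles: Sequence[str],
                  protein_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Replay the preparation recipe on raw SMILES."""
        blocks = []
        for dset in self.descriptor_sets:
            blocks.append(dset.transform_smiles(list(smiles))
                          .reset_index(drop=True))
        if self.is_pcm:
            if protein_ids is None:
                raise ValueError("PCM model requires protein_ids")
            unknown = set(protein_ids) - set(self.protein_sequences)
            if unknown:
                raise KeyError(
                    f"unknown protein ids: {sorted(unknown)}")
            for pset in self.protein_descriptor_sets:
                per_protein = pset.transform_sequences(self.protein_sequences)
                rows = per_protein.loc[list(protein_ids)].reset_index(drop=True)
                blocks.append(rows)
        full = pd.concat(blocks, axis=1)
        out = full.reindex(columns=self.feature_names)
        if self.imputation:
            out = out.fillna(pd.Series(self.imputation))
        if self.standardizer is not None:
            out = self.standardizer.transform(out)
        return out

    def predict_from_smiles(self, smiles: Sequence[str],
                            protein_ids: Sequence[str] | None = None
                            ) -> pd.DataFrame:
        """Predict for raw SMILES, row-aligned to the input.

        Invalid SMILES yield NaN predictions and ``valid = False``; with
        an attached applicability domain an ``in_domain`` flag is added.
        """
        if not self.is_fitted:
            raise RuntimeError(f"model {self.name!r} is not fitted")
        smiles = list(smiles)
        valid = np.array([isinstance(s, str) and
                          Chem.MolFromSmiles(s) is not None for s in smiles])
        n = len(smiles)
        out = pd.DataFrame({"smiles": smiles, "valid": valid})
        pred_cols = [f"{tp.name}_Prediction" for tp in self.target_properties]
        for c in pred_cols:
            out[c] = np.nan
        proba_cols = [c for c in self.output_columns if "ProbabilityClass" in c]
        for c in proba_cols:
            out[c] = np.nan
        if self.applicability_domain is not None:
            out["in_domain"] = pd.array([None] * n, dtype="boolean")
        if valid.any():
            idx = np.flatnonzero(valid)
            sub_prot = ([protein_ids[i] for i in idx]
                        if protein_ids is not None else None)
            feats = self.featurize([smiles[i] for i in idx], sub_prot)
            X = feats.to_numpy(dtype=float)
            preds = self.predict(X)
            for j, c in enumerate(pred_cols):
                out.loc[idx, c] = preds[:, j]
            if proba_cols:
                probas = self.predict_proba(X)
                flat = np.concatenate(probas, axis=1)
                for j, c in enumerate(proba_cols):
                    out.loc[idx, c] = flat[:, j]
            if self.applicability_domain is not None:
                flags = self.applicability_domain.contains(X)
                out.loc[idx, "in_domain"] = flags
        return out

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = []
        payload_hashes = []
        for i, est in enumerate(self.estimators_):
            fname = f"estimator_{i}.joblib"
            path = directory / fname
            if self._payload_bytes is not None:
                path.write_bytes(self._payload_bytes[i])
            else:
                joblib.dump(est, path)
            files.append(fname)
            payload_hashes.append(persistence.content_hash(path))
        meta = {
            "class": type(self).__name__,
            "name": self.name,
            "random_state": self.random_state,
            "task": self.task.value if self.task else None,
            "estimator_spec": self.estimator_spec(),
            "target_properties": [tp.to_config()
                                  for tp in self.target_properties],
            "descriptors": [d.to_config() for d in self.descriptor_sets],
            "protein_descriptors": [d.to_config()
                                    for d in self.protein_descriptor_sets],
            "protein_sequences": self.protein_sequences,
            "feature_names": self.feature_names,
            "imputation": self.imputation,
            "standardizer": (self.standardizer.to_config()
                             if self.standardizer else None),
            "applicability_domain": (self.applicability_domain.to_config()
                                     if self.applicability_domain else None),
            "metadata": self.metadata,
            "is_fitted": self.is_fitted,
            "files": files,
            "payload_hashes": payload_hashes,
        }
        return persistence.save_meta(directory, meta)

    @classmethod
    def load(cls, directory: str | Path) -> "QSARModel":
        directory = Path(directory)
        meta = persistence.load_meta(directory)
        klass = MODEL_CLASSES[meta["class"]]
        model = klass._from_meta(meta)
        model.task = ModelTask[meta["task"]] if meta["task"] else None
        model.target_properties = [TargetProperty.from_config(c)
                                   for c in meta["target_properties"]]
        model.descriptor_sets = [descriptor_from_config(c)
                                 for c in meta["descriptors"]]
        model.protein_descriptor_sets = [
            descriptor_from_config(c) for c in meta["protein_descriptors"]]
        model.protein_sequences = meta.get("protein_sequences") or {}
        model.feature_names = meta["feature_names"]
        model.imputation = meta["imputation"] or {}
        if meta["standardizer"]:
            model.standardizer = FeatureStandardizer.from_config(
                meta["standardizer"])
        if meta["applicability_domain"]:
            model.applicability_domain = ad_from_config(
                meta["applicability_domain"])
        model.metadata = meta["metadata"]
        model.y_imputation = meta["metadata"].get("y_imputation", {})
        model.is_fitted = meta["is_fitted"]
        model.estimators_ = []
        model._payload_bytes = []
        for fname in meta["files"]:
            path = directory / fname
            model.estimators_.append(joblib.load(path))
            model._payload_bytes.append(path.read_bytes())
        return model

    @classmethod
    def _from_meta(cls, meta: dict) -> "QSARModel":
        return cls(meta["name"], meta["random_state"])


class SklearnModel(QSARModel):
    """Wrapper adapting the fit/predict estimator convention.

    The algorithm is referenced by registry name so hyperparameters and
    the full specification round-trip through JSON metadata.
    """

    def __init__(self, name: str, algorithm: str,
                 params: dict | None = None,
                 random_state: int | None = None):
        super().__init__(name, random_state)
        if algorithm not in ALGORITHMS:
            raise KeyError(
                f"unknown algorithm {algorithm!r}; registered: "
                f"{sorted(ALGORITHMS)}")
        self.algorithm = algorithm
        self.params = dict(params or {})

    def _make_estimator(self):
        klass = ALGORITHMS[self.algorithm]
        params = dict(self.params)
        if "random_state" in klass().get_params() and \
                "random_state" not in params:
            params["random_state"] = self.random_state
        return klass(**params)

    def estimator_spec(self) -> dict:
        return {"class": "SklearnModel", "algorithm": self.algorithm,
                "params": self.params}

    def clone(self) -> "SklearnModel":
        out = SklearnModel(self.name, self.algorithm, dict(self.params),
                           self.random_state)
        out.task = self.task
        return out

    @classmethod
    def _from_meta(cls, meta: dict) -> "SklearnModel":
        spec = meta["estimator_spec"]
        return cls(meta["name"], spec["algorithm"], spec["params"],
                   meta["random_state"])


class MedianBaseline(QSARModel):
    """Constant baseline predicting the training median of each task.

    For a regression test set with non-zero variance its coefficient of
    determination is at most zero (exactly zero only when the test and
    training medians coincide with the test mean), making it a floor any
    informative model must clear.
    """

    def __init__(self, name: str = "MedianBaseline",
                 random_state: int | None = None):
        super().__init__(name, random_state)
        self.medians_: np.ndarray | None = None

    def fit(self, dataset: QSARDataset) -> "MedianBaseline":
        if not dataset.task.is_regression:
            raise ValueError("median baseline supports regression tasks only")
        return super().fit(dataset)

    def _fit_arrays(self, X: np.ndarray, y: pd.DataFrame) -> None:
        self.medians_ = np.nanmedian(y.to_numpy(dtype=float), axis=0)
        self.estimators_ = [_ConstantEstimator(m) for m in self.medians_]
        self.y_imputation = {}

    def clone(self) -> "MedianBaseline":
        return MedianBaseline(self.name, self.random_state)

    @classmethod
    def _from_meta(cls, meta: dict) -> "MedianBaseline":
        return cls(meta["name"], meta["random_state"])


class _ConstantEstimator:
    """Predicts one constant; exists so baselines share the per-task
    estimator composition and joblib payload path."""

    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value)


class PCMModel(QSARModel):
    """Proteochemometric model over compound–protein pairs.

    Prediction requires a protein identifier known to the registry of
    sequences captured from the training dataset.
    """

    def __init__(self, name: str, algorithm: str = "RandomForestRegressor",
                 params: dict | None = None,
                 random_state: int | None = None):
        super().__init__(name, random_state)
        if algorithm not in ALGORITHMS:
            raise KeyError(f"unknown algorithm {algorithm!r}; registered: "
                           f"{sorted(ALGORITHMS)}")
        self.algorithm = algorithm
        self.params = dict(params or {})

    def fit(self, dataset: QSARDataset) -> "PCMModel":
        if not isinstance(dataset, PCMDataset):
            raise TypeError("PCMModel requires a PCMDataset")
        return super().fit(dataset)

    _make_estimator = SklearnModel._make_estimator

    def estimator_spec(self) -> dict:
        return {"class": "PCMModel", "algorithm": self.algorithm,
                "params": self.params}

    def clone(self) -> "PCMModel":
        out = PCMModel(self.name, self.algorithm, dict(self.params),
                       self.random_state)
        out.task = self.task
        return out

    @classmethod
    def _from_meta(cls, meta: dict) -> "PCMModel":
        spec = meta["estimator_spec"]
        return cls(meta["name"], spec["algorithm"], spec["params"],
                   meta["random_state"])


MODEL_CLASSES = {
    "SklearnModel": SklearnModel,
    "MedianBaseline": MedianBaseline,
    "PCMModel": PCMModel,
}
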