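"""Row-level data filters and training-set-fitted feature selection.

Data filters map a dataset to a subset of retained rows and are
idempotent. Feature filters and the standardizer are fitted on training
rows only — never on test rows — and their fitted state is stored in the
preparation recipe so deployment-time featurization replays exactly.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Row filters

class DataFilter(ABC):
    """Maps a dataset table to retained positional row indices."""

    name: str

    @abstractmethod
    def filter(self, table: pd.DataFrame, dataset=None) -> np.ndarray: ...

    @abstractmethod
    def to_config(self) -> dict: ...


class CategoryFilter(DataFilter):
    """Keep or remove rows by membership of a column's value in a set."""

    def __init__(self, column: str, values, keep: bool = False):
        self.column = column
        self.values = set(values)
        self.keep = keep
        self.name = f"CategoryFilter_{column}"

    def filter(self, table: pd.DataFrame, dataset=None) -> np.ndarray:
        if self.column not in table.columns:
            raise KeyError(f"unknown column {self.column!r}")
        member = table[self.column].isin(self.values).to_numpy()
        mask = member if self.keep else ~member
        return np.flatnonzero(mask)

    def to_config(self) -> dict:
        return {"type": "category", "column": self.column,
                "values": sorted(self.values, key=repr), "keep": self.keep}


class RepeatsFilter(DataFilter):
    """Resolve rows with identical descriptor vectors.

    Rows are grouped by exact descriptor equality. Singletons are kept.
    Within a duplicate group the first row (input order) is kept when
    all target values agree — exact equality for class labels, absolute
    tolerance 1e-9 for regression — otherwise the entire group is
    dropped as irreconcilable label noise.
    """

    name = "RepeatsFilter"

    def __init__(self, target_columns: list[str] | None = None, atol: float = 1e-9):
        self.target_columns = target_columns
        self.atol = atol

    def filter(self, table: pd.DataFrame, dataset=None,
               descriptors: pd.DataFrame | None = None) -> np.ndarray:
        if descriptors is None:
            if dataset is None or dataset.descriptor_matrix() is None:
                raise ValueError("RepeatsFilter needs a computed descriptor matrix")
            descriptors = dataset.descriptor_matrix()
        targets = self.target_columns
        if targets is None and dataset is not None:
            targets = [tp.label_column for tp in dataset.target_properties]
        targets = targets or []
        groups: dict[tuple, list[int]] = {}
        mat = descriptors.to_numpy()
        for i in range(len(mat)):
            groups.setdefault(tuple(mat[i]), []).append(i)
        keep: list[int] = []
        for members in groups.values():
            if len(members) == 1:
                keep.append(members[0])
                continue
            consistent = True
            for col in targets:
                vals = table[col].to_numpy()[members]
                if pd.api.types.is_numeric_dtype(table[col]):
                    if np.nanmax(vals) - np.nanmin(vals) > self.atol:
                        consistent = False
                        break
                elif len(set(vals)) > 1:
                    consistent = False
                    break
            if consistent:
                keep.append(members[0])
        return np.array(sorted(keep), dtype=int)

    def to_config(self) -> dict:
        return {"type": "repeats", "atol": self.atol}


def data_filter_from_config(cfg: dict) -> DataFilter:
    if cfg["type"] == "category":
        return CategoryFilter(cfg["column"], cfg["values"], cfg["keep"])
    if cfg["type"] == "repeats":
        return RepeatsFilter(atol=cfg.get("atol", 1e-9))
    raise ValueError(f"unknown data filter type {cfg['type']!r}")


# ---------------------------------------------------------------------------
# Feature filters

class FeatureFilter(ABC):
    """Selects feature columns; fitted on training rows only."""

    name: str
    selected_: list[str] | None = None

    @abstractmethod
    def fit(self, train_features: pd.DataFrame) -> "FeatureFilter": ...

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if self.selected_ is None:
            raise RuntimeError(f"{self.name} is not fitted")
        return features[self.selected_]

    @abstractmethod
    def to_config(self) -> dict: ...


class LowVarianceFilter(FeatureFilter):
    """Drop features whose training-set population variance is <= threshold."""

    def __init__(self, threshold: float = 0.0):
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        self.threshold = float(threshold)
        self.name = "LowVarianceFilter"

    def fit(self, train_features: pd.DataFrame) -> "LowVarianceFilter":
        var = train_features.to_numpy(dtype=float).var(axis=0, ddof=0)
        self.selected_ = [c for c, v in zip(train_features.columns, var)
                          if v > self.threshold]
        return self

    def to_config(self) -> dict:
        return {"type": "low_variance", "threshold": self.threshold,
                "selected": self.selected_}


class HighCorrelationFilter(FeatureFilter):
    """Drop the later of any feature pair with |Pearson r| above threshold.

    Pairs are scanned in column order, so the selection is deterministic
    and order-stable. Zero-variance columns are excluded from the
    correlation scan and kept (the variance filter owns them).
    """

    def __init__(self, threshold: float = 0.95):
        if not 0 < threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        self.threshold = float(threshold)
        self.name = "HighCorrelationFilter"

    def fit(self, train_features: pd.DataFrame) -> "HighCorrelationFilter":
        cols = list(train_features.columns)
        mat = train_features.to_numpy(dtype=float)
        sd = mat.std(axis=0, ddof=0)
        varying = sd > 0
        dropped: set[int] = set()
        idx = [i for i in range(len(cols)) if varying[i]]
        if idx:
            sub = mat[:, idx]
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(sub, rowvar=False)
            corr = np.atleast_2d(corr)
            for a in range(len(idx)):
                if idx[a] in dropped:
                    continue
                for b in range(a + 1, len(idx)):
                    if idx[b] in dropped:
                        continue
                    if abs(corr[a, b]) > self.threshold:
                        dropped.add(idx[b])
        self.selected_ = [c for i, c in enumerate(cols) if i not in dropped]
        return self

    def to_config(self) -> dict:
        return {"type": "high_correlation", "threshold": self.threshold,
                "selected": self.selected_}


def feature_filter_from_config(cfg: dict) -> FeatureFilter:
    if cfg["type"] == "low_variance":
        f = LowVarianceFilter(cfg["threshold"])
    elif cfg["type"] == "high_correlation":
        f = HighCorrelationFilter(cfg["threshold"])
    else:
        raise ValueError(f"unknown feature filter type {cfg['type']!r}")
    f.selected_ = cfg.get("selected")
    return f


# ---------------------------------------------------------------------------
# Standardizer

class FeatureStandardizer:
    """Center/scale features by training-set mean and standard deviation.

    Constant columns pass through unscaled (scale := 1) so binary or
    degenerate features never produce division by zero. Test rows are
    always transformed with the training state.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.columns_: list[str] | None = None

    @property
    def is_fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, train_features: pd.DataFrame) -> "FeatureStandardizer":
        mat = train_features.to_numpy(dtype=float)
        self.mean_ = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        self.columns_ = list(train_features.columns)
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if not self.is_fitted:
            raise RuntimeError("standardizer is not fitted")
        mat = features[self.columns_].to_numpy(dtype=float)
        out = (mat - self.mean_) / self.scale_
        return pd.DataFrame(out, columns=self.columns_, index=features.index)

    def inverse_transform(self, features: pd.DataFrame) -> pd.DataFrame:
        mat = features[self.columns_].to_numpy(dtype=float)
        out = mat * self.scale_ + self.mean_
        return pd.DataFrame(out, columns=self.columns_, index=features.index)

    def to_config(self) -> dict:
        return {"mean": None if self.mean_ is None else self.mean_.tolist(),
                "scale": None if self.scale_ is None else self.scale_.tolist(),
                "columns": self.columns_}

    @classmethod
    def from_config(cls, cfg: dict) -> "FeatureStandardizer":
        out = cls()
        if cfg.get("mean") is not None:
            out.mean_ = np.asarray(cfg["mean"], dtype=float)
            out.scale_ = np.asarray(cfg["scale"], dtype=float)
            out.columns_ = list(cfg["columns"])
        return out
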