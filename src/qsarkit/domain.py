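"""Applicability-domain definitions.

An applicability domain (AD) is fitted on training-set features and then
flags query points as in- or out-of-domain. Two canonical definitions
are provided: a per-feature bounding box and a k-nearest-neighbour
distance domain whose threshold is the 95th percentile of each training
point's mean Euclidean distance to its k nearest training neighbours
(self excluded). The base contract is open for further definitions.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
from sklearn.neighbors import NearestNeighbors


class ApplicabilityDomain(ABC):
    """Fit on training features; decide membership per query row."""

    kind: str
    is_fitted: bool = False

    @abstractmethod
    def fit(self, train_features: np.ndarray) -> "ApplicabilityDomain": ...

    @abstractmethod
    def contains(self, features: np.ndarray) -> np.ndarray: ...

    @abstractmethod
    def to_config(self) -> dict: ...

    def _check(self, features: np.ndarray, width: int) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError(f"{self.kind} applicability domain not fitted")
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != width:
            raise ValueError(
                f"feature width {features.shape[1]} != fitted width {width}")
        return features


class BoundingBoxAD(ApplicabilityDomain):
    """In-domain iff every feature lies within the training [min, max]."""

    kind = "bounding_box"

    def __init__(self):
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    def fit(self, train_features: np.ndarray) -> "BoundingBoxAD":
        mat = np.atleast_2d(np.asarray(train_features, dtype=float))
        if mat.size == 0 or not np.isfinite(mat).all():
            raise ValueError("training features must be non-empty and finite")
        self.min_ = mat.min(axis=0)
        self.max_ = mat.max(axis=0)
        self.is_fitted = True
        return self

    def contains(self, features: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError(f"{self.kind} applicability domain not fitted")
        mat = self._check(features, len(self.min_))
        return ((mat >= self.min_) & (mat <= self.max_)).all(axis=1)

    def to_config(self) -> dict:
        return {"kind": self.kind,
                "min": None if self.min_ is None else self.min_.tolist(),
                "max": None if self.max_ is None else self.max_.tolist()}


class KNNDistanceAD(ApplicabilityDomain):
    """k-NN mean-distance domain with a percentile threshold.

    The threshold is the ``percentile``-th percentile (default 95) of
    each training point's mean Euclidean distance to its ``k`` nearest
    training neighbours, self excluded; a query is in-domain iff its
    mean distance to the k nearest training points is at or below it.
    """

    kind = "knn_distance"

    def __init__(self, k: int = 5, percentile: float = 95.0):
        self.k = int(k)
        self.percentile = float(percentile)
        self.train_: np.ndarray | None = None
        self.threshold_: float | None = None

    def fit(self, train_features: np.ndarray) -> "KNNDistanceAD":
        mat = np.atleast_2d(np.asarray(train_features, dtype=float))
        if len(mat) < self.k + 1:
            raise ValueError(
                f"need at least k+1={self.k + 1} training rows, got {len(mat)}")
        if not np.isfinite(mat).all():
            raise ValueError("training features must be finite")
        nn = NearestNeighbors(n_neighbors=self.k + 1).fit(mat)
        dists, _ = nn.kneighbors(mat)
        mean_dists = dists[:, 1:].mean(axis=1)  # drop self (distance 0)
        self.threshold_ = float(np.percentile(mean_dists, self.percentile))
        self.train_ = mat
        self.is_fitted = True
        return self

    def contains(self, features: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError(f"{self.kind} applicability domain not fitted")
        mat = self._check(features, self.train_.shape[1])
        nn = NearestNeighbors(n_neighbors=self.k).fit(self.train_)
        dists, _ = nn.kneighbors(mat)
        return dists.mean(axis=1) <= self.threshold_

    def to_config(self) -> dict:
        return {"kind": self.kind, "k": self.k, "percentile": self.percentile,
                "threshold": self.threshold_,
                "train": None if self.train_ is None else self.train_.tolist()}


def ad_from_config(cfg: dict) -> ApplicabilityDomain:
    if cfg["kind"] == "bounding_box":
        ad = BoundingBoxAD()
        if cfg.get("min") is not None:
            ad.min_ = np.asarray(cfg["min"], dtype=float)
            ad.max_ = np.asarray(cfg["max"], dtype=float)
            ad.is_fitted = True
        return ad
    if cfg["kind"] == "knn_distance":
        ad = KNNDistanceAD(cfg["k"], cfg["percentile"])
        if cfg.get("train") is not None:
            ad.train_ = np.asarray(cfg["train"], dtype=float)
            ad.threshold_ = cfg["threshold"]
            ad.is_fitted = True
        return ad
    raise ValueError(f"unknown applicability domain kind {cfg['kind']!r}")
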