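"""One-class (novelty-detection) baselines.

Five classic one-class families, all exposed through the same score/threshold
interface — higher score means more anomalous, a sample is accepted iff its
score does not exceed the threshold, and the threshold is the empirical
(1 − rejection_rate) quantile of the training scores:

* ``parzen``    — negative Parzen-window (Gaussian kernel) density;
* ``knn_oc``    — distance to the j-th nearest training sample;
* ``kmeans_oc`` — distance to the nearest k-means centroid;
* ``pca_oc``    — reconstruction error from the retained principal components;
* ``svdd``      — distance-like score from an RBF-kernel enclosing-sphere
  (one-class SVM) decision function.

Two usage schemes aggregate them over a multi-phenotype target class:
MOCV trains one model per subclass and rejects only if every model rejects;
SOCMT trains a single model on all subclasses pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import KernelDensity, NearestNeighbors
from sklearn.svm import OneClassSVM

from .data import ConfigurationError

__all__ = [
    "OneClassModel",
    "OneClassEnsemble",
    "fit_one_class",
    "one_class_scores",
    "predict_mocv",
    "predict_socmt",
    "ONE_CLASS_METHODS",
]

ONE_CLASS_METHODS = ("parzen", "knn_oc", "kmeans_oc", "pca_oc", "svdd")


@dataclass
class OneClassModel:
    method: str
    fitted: dict
    score_threshold: float
    training_rejection_rate: float
    n_features: int

    def __post_init__(self) -> None:
        if self.method not in ONE_CLASS_METHODS:
            raise ConfigurationError(f"method must be one of {ONE_CLASS_METHODS}")
        if not (0 <= self.training_rejection_rate < 0.5):
            raise ConfigurationError("training_rejection_rate must lie in [0, 0.5)")


@dataclass
class OneClassEnsemble:
    mode: str                      # "MOCV" or "SOCMT"
    models: list[OneClassModel]

    def __post_init__(self) -> None:
        if self.mode not in ("MOCV", "SOCMT"):
            raise ConfigurationError("mode must be 'MOCV' or 'SOCMT'")
        if self.mode == "MOCV" and len(self.models) < 2:
            raise ConfigurationError("MOCV needs at least 2 member models")
        if self.mode == "SOCMT" and len(self.models) != 1:
            raise ConfigurationError("SOCMT needs exactly 1 model")


def _raw_scores(method: str, fitted: dict, X: np.ndarray) -> np.ndarray:
    if method == "parzen":
        kde: KernelDensity = fitted["kde"]
        return -np.exp(kde.score_samples(X))
    if method == "knn_oc":
        nn: NearestNeighbors = fitted["nn"]
        j = fitted["j"]
        # query one extra neighbour so an exact self-match in the training
        # set can be skipped (leave-one-out semantics for training points)
        dist, _ = nn.kneighbors(X, n_neighbors=min(j + 1, fitted["n_train"]))
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            d = dist[i]
            if d[0] == 0.0 and d.size > j:
                out[i] = d[j]
            else:
                out[i] = d[min(j, d.size) - 1]
        return out
    if method == "kmeans_oc":
        km: KMeans = fitted["km"]
        return np.min(km.transform(X), axis=1)
    if method == "pca_oc":
        mean = fitted["mean"]
        comps = fitted["components"]  # (q × p)
        Z = X - mean
        recon = (Z @ comps.T) @ comps
        return np.linalg.norm(Z - recon, axis=1)
    # svdd: larger decision_function = deeper inside the sphere
    svm: OneClassSVM = fitted["svm"]
    return -svm.decision_function(X)


def fit_one_class(
    samples: np.ndarray,
    method: str,
    params: dict | None = None,
    rejection_rate: float = 0.1,
    seed: int = 0,
) -> OneClassModel:
    """Fit one novelty-detection model and calibrate its acceptance threshold
    so that a ``rejection_rate`` fraction of the training set would be
    rejected (empirical quantile of the training scores).

    Method hyperparameters (``params``) default to rule-of-thumb values:
    Scott bandwidth for Parzen, j=1 for knn_oc, min(5, n//2) clusters, 90%
    retained variance for pca_oc, and an RBF one-class SVM with nu matched to
    the rejection rate for svdd.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("samples must be a 2-D matrix")
    n, p = X.shape
    if n < 5:
        raise ConfigurationError("need at least 5 training samples")
    if not (0 <= rejection_rate < 0.5):
        raise ConfigurationError("rejection_rate must lie in [0, 0.5)")
    params = dict(params or {})

    if method == "parzen":
        bw = params.get("bandwidth")
        if bw is None:
            sd = float(np.mean(np.std(X, axis=0, ddof=1)))
            bw = max(sd, 1e-6) * n ** (-1.0 / (p + 4))  # Scott's rule
        kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(X)
        fitted = {"kde": kde, "bandwidth": bw}
    elif method == "knn_oc":
        j = int(params.get("j", 1))
        if not (1 <= j < n):
            raise ConfigurationError("knn_oc needs 1 <= j < n_samples")
        nn = NearestNeighbors().fit(X)
        fitted = {"nn": nn, "j": j, "n_train": n}
    elif method == "kmeans_oc":
        k = int(params.get("n_clusters", min(5, n // 2)))
        if not (1 <= k <= n):
            raise ConfigurationError("kmeans_oc cluster count must lie in [1, n]")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        fitted = {"km": km, "n_clusters": k}
    elif method == "pca_oc":
        frac = float(params.get("variance_retained", 0.9))
        mean = X.mean(axis=0)
        _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
        var = s**2
        rank = max(1, int(np.sum(s > s[0] * 1e-9)))
        ratios = np.cumsum(var[:rank]) / var[:rank].sum()
        q = int(np.searchsorted(ratios, frac - 1e-12) + 1)
        q = min(max(1, q), max(1, rank - 1))  # keep a residual subspace
        fitted = {"mean": mean, "components": vt[:q].copy(), "q": q}
    elif method == "svdd":
        nu = float(params.get("nu", max(rejection_rate, 0.01)))
        gamma = params.get("gamma", "scale")
        svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma).fit(X)
        fitted = {"svm": svm}
    else:
        raise ConfigurationError(f"unknown one-class method {method!r}")

    train_scores = _raw_scores(method, fitted, X)
    if method == "parzen":
        # calibrate on leave-one-out densities: the self-kernel otherwise makes
        # every training point look far denser than any test point can be
        k0 = (2 * np.pi * fitted["bandwidth"] ** 2) ** (-p / 2)
        loo = (n * (-train_scores) - k0) / (n - 1)
        train_scores = -np.clip(loo, 0.0, None)
    threshold = float(np.quantile(train_scores, 1 - rejection_rate))
    model = OneClassModel(
        method=method,
        fitted=fitted,
        score_threshold=threshold,
        training_rejection_rate=rejection_rate,
        n_features=p,
    )
    model.fitted["train_scores"] = train_scores
    return model


def one_class_scores(model: OneClassModel, samples: np.ndarray) -> np.ndarray:
    """Anomaly scores (higher = more anomalous); accept iff score <= threshold."""
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ConfigurationError(
            f"expected {model.n_features} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    return _raw_scores(model.method, model.fitted, X)


def _accepts(model: OneClassModel, samples: np.ndarray) -> np.ndarray:
    return one_class_scores(model, samples) <= model.score_threshold


def predict_mocv(ensemble: OneClassEnsemble, samples: np.ndarray) -> np.ndarray:
    """Multi one-class with voting: reject iff *every* member rejects."""
    if ensemble.mode != "MOCV":
        raise ConfigurationError("predict_mocv requires a MOCV ensemble")
    acc = np.column_stack([_accepts(m, samples) for m in ensemble.models])
    return acc.any(axis=1)


def predict_socmt(ensemble: OneClassEnsemble, samples: np.ndarray) -> np.ndarray:
    """Single one-class over pooled subclasses: the member decides alone."""
    if ensemble.mode != "SOCMT":
        raise ConfigurationError("predict_socmt requires a SOCMT ensemble")
    return _accepts(ensemble.models[0], samples)
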