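"""Multi-class classifiers with class-probability estimates.

Three families commonly used on expression profiles are supported, each with
the simple probability-estimate convention the decision rules consume:

* **k-NN** — the estimate for a class is the fraction of the k nearest
  training neighbours carrying that class (multiples of 1/k);
* **random forest** — the fraction of trees voting for the class (multiples
  of 1/n_trees; votes are counted explicitly per tree rather than averaging
  leaf posteriors);
* **single-hidden-layer network** — per-class outputs renormalized to sum
  to one.

Hyperparameters are selected by leave-group-out cross-validation: repeated
random train/holdout splits, the candidate maximizing mean holdout accuracy
wins, ties going to the simplest candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .data import ConfigurationError

__all__ = [
    "ProbEstimateMatrix",
    "TrainConfig",
    "ProbabilisticClassifier",
    "train_probabilistic_classifier",
    "predict_class_probabilities",
]

ALGORITHMS = ("knn", "rf", "nnet")


@dataclass
class ProbEstimateMatrix:
    """Per-sample class-probability vectors from a trained classifier."""

    class_ids: list[str]
    probs: np.ndarray                  # (n_samples × n_classes)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(set(self.class_ids)) != len(self.class_ids):
            raise ConfigurationError("class_ids must be unique")
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.class_ids):
            raise ConfigurationError("probs must be n_samples × n_classes")
        if self.probs.shape[0] != len(self.sample_ids):
            raise ConfigurationError("one probability row per sample id required")
        if np.any(self.probs < -1e-9) or np.any(self.probs > 1 + 1e-9):
            raise ConfigurationError("probability entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ConfigurationError("every probability row must sum to 1 (±1e-6)")


@dataclass
class TrainConfig:
    """Training/model-selection settings.

    Defaults follow the leave-group-out convention: 5 candidate models per
    family, each scored over 30 random splits holding out 2% of the samples.
    """

    algorithm: str = "rf"
    n_candidates: int = 5
    resampling_repeats: int = 30
    train_fraction: float = 0.98
    n_trees: int = 500                 # random-forest ensemble size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"algorithm must be one of {ALGORITHMS}")
        if self.n_candidates < 1:
            raise ConfigurationError("n_candidates must be >= 1")
        if self.resampling_repeats < 1:
            raise ConfigurationError("resampling_repeats must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


@dataclass
class ProbabilisticClassifier:
    """A fitted model plus the metadata needed to predict probabilities."""

    algorithm: str
    estimator: object
    class_ids: list[str]
    n_features: int
    chosen_params: dict

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ProbabilisticClassifier":
        return joblib.load(path)


def _candidate_grid(algorithm: str, n_candidates: int, n_train: int, n_features: int):
    """Ordered candidate parameter sets, simplest first (ties go to index 0)."""
    if algorithm == "knn":
        ks = [5 + 2 * i for i in range(n_candidates)]
        ks = [min(k, max(1, n_train - 1)) for k in ks]
        return [{"n_neighbors": k} for k in dict.fromkeys(ks)]
    if algorithm == "rf":
        if n_candidates == 1:
            # single candidate: the usual sqrt(p) features-per-split default
            return [{"max_features": max(1, int(round(np.sqrt(n_features))))}]
        mtry = np.unique(
            np.linspace(
                max(1, int(round(np.sqrt(n_features) / 2))), n_features, n_candidates
            ).round().astype(int)
        )
        return [{"max_features": int(m)} for m in mtry]
    # nnet: joint (hidden size, weight decay) candidates
    sizes = [1, 3, 5, 7, 9][:n_candidates]
    decays = [0.1, 0.01, 1e-3, 1e-4, 0.0][:n_candidates]
    return [{"hidden": s, "decay": d} for s, d in zip(sizes, decays)]


def _build(algorithm: str, params: dict, n_trees: int, seed: int):
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=params["n_neighbors"], weights="uniform")
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features=params["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    return MLPClassifier(
        hidden_layer_sizes=(params["hidden"],),
        alpha=params["decay"],
        solver="lbfgs",
        max_iter=500,
        random_state=seed,
    )


def train_probabilistic_classifier(
    X: np.ndarray, labels: Sequence[str], config: TrainConfig
) -> ProbabilisticClassifier:
    """Select hyperparameters by repeated random holdouts, then fit on all data.

    Deterministic for a fixed ``config.seed``.  Every class needs at least two
    samples so it can appear on both sides of a resampling split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(l) for l in labels], dtype=object)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ConfigurationError("X must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ConfigurationError("need at least 2 classes to train a classifier")
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise ConfigurationError(
            f"class {bad!r} has a single sample; cannot resample"
        )

    grid = _candidate_grid(config.algorithm, config.n_candidates, X.shape[0], X.shape[1])
    if len(grid) > 1:
        splitter = ShuffleSplit(
            n_splits=config.resampling_repeats,
            train_size=config.train_fraction,
            random_state=config.seed,
        )
        splits = list(splitter.split(X))
        scores = []
        for params in grid:
            accs = []
            for tr, te in splits:
                est = _build(config.algorithm, params, config.n_trees, config.seed)
                est.fit(X[tr], y[tr])
                accs.append(float(np.mean(est.predict(X[te]) == y[te])))
            scores.append(float(np.mean(accs)))
        best = int(np.argmax(scores))   # first maximum: simplest candidate wins ties
    else:
        best = 0
    chosen = grid[best]
    est = _build(config.algorithm, chosen, config.n_trees, config.seed)
    est.fit(X, y)
    return ProbabilisticClassifier(
        algorithm=config.algorithm,
        estimator=est,
        class_ids=[str(c) for c in est.classes_],
        n_features=X.shape[1],
        chosen_params=chosen,
    )


def predict_class_probabilities(
    model: ProbabilisticClassifier,
    X: np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> ProbEstimateMatrix:
    """Class-probability estimates under the per-family conventions above."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ConfigurationError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    est = model.estimator
    k_classes = len(model.class_ids)
    if model.algorithm == "rf":
        # explicit vote fraction: trees predict in the encoded class space 0..k-1
        votes = np.zeros((X.shape[0], k_classes))
        for tree in est.estimators_:
            pred = tree.predict(X).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1
        probs = votes / len(est.estimators_)
    else:
        probs = np.asarray(est.predict_proba(X), dtype=float)
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    return ProbEstimateMatrix(
        class_ids=list(model.class_ids), probs=probs, sample_ids=list(sample_ids)
    )
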