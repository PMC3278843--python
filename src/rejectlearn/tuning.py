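"""Threshold setup: leave-one-class-out folds, objectives, CMA-ES tuning.

At training time no genuine reject samples exist, so the tuning sample is
manufactured from the training set itself: each of the k trained classes in
turn plays the reject set R, the remaining classes form the reduced target
set T', and m folds per held-out class each remove x samples per remaining
class (the fold's target test set, x·(k−1) samples) plus x samples of R (the
fold's reject test set).  Every fold runs an independent preprocessing +
classification experiment on Train* = T' minus the fold's test targets, and
the (max1, max2) pair of every test sample is recorded together with its
target/reject truth.

The three thresholds are then chosen by minimizing an objective built from
the sensitivity and specificity of the decision rules on that tuning sample:

* ``SS``  = (1 − Sens) + (1 − Spec)
* ``SS1`` = (1 − Sens)² + (1 − Spec)²   (the recommended default)
* ``SS2`` = max(1 − Sens, 1 − Spec)
* ``FS1``/``FS05`` = 1 − F_β  (β = 1 or 0.5) from precision and recall

all minimized by CMA-ES over the (T_max, T_rej, T_diff) box, with candidates
violating T_rej < T_max or the [0, 1] box given penalty 2 + violation (above
every feasible value).  An objective of 0 means perfect target/reject
discrimination on the tuning sample; the achieved value is therefore a
reliability indicator for the trained rejector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cmaes import CMAESConfig, cmaes_minimize
from .classifiers import TrainConfig, predict_class_probabilities, train_probabilistic_classifier
from .data import ConfigurationError, LabeledExpressionDataset
from .evaluation import ConfusionSummary
from .preprocess import apply_preprocessor, fit_preprocessor
from .rejection import RejectionThresholds, top_two

__all__ = [
    "FoldSpec",
    "TuningRecord",
    "TuningSample",
    "ObjectiveSpec",
    "CMAESConfig",
    "generate_rejection_folds",
    "collect_tuning_sample",
    "objective_value",
    "confusion_from_records",
    "optimize_thresholds",
]

OBJECTIVE_NAMES = ("SS", "SS1", "SS2", "FS1", "FS05")


@dataclass(frozen=True)
class FoldSpec:
    """One threshold-setup fold: the held-out class plays the reject set."""

    held_out_class: str
    fold_index: int
    train_sample_ids: tuple[str, ...]
    test_target_ids: tuple[str, ...]
    test_reject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        train = set(self.train_sample_ids)
        test = set(self.test_target_ids) | set(self.test_reject_ids)
        if train & test:
            raise ConfigurationError("fold train and test sets must be disjoint")


@dataclass(frozen=True)
class TuningRecord:
    max1: float
    max2: float
    is_target: bool
    fold: FoldSpec | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.max2 <= self.max1 <= 1.0):
            raise ConfigurationError(
                f"record violates 0 <= max2 <= max1 <= 1: ({self.max1}, {self.max2})"
            )
        if self.max1 + self.max2 > 1.0 + 1e-9:
            raise ConfigurationError("record violates max1 + max2 <= 1")


@dataclass
class TuningSample:
    """Class-probability top-two statistics harvested across folds."""

    records: list[TuningRecord]

    def __post_init__(self) -> None:
        flags = [r.is_target for r in self.records]
        if not any(flags) or all(flags):
            raise ConfigurationError(
                "tuning sample needs at least one target and one reject record"
            )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        max1 = np.array([r.max1 for r in self.records])
        max2 = np.array([r.max2 for r in self.records])
        is_target = np.array([r.is_target for r in self.records], dtype=bool)
        return max1, max2, is_target


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which tuning objective to minimize; β is fixed by the FS variant."""

    name: str = "SS1"
    beta: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.name not in OBJECTIVE_NAMES:
            raise ConfigurationError(f"objective must be one of {OBJECTIVE_NAMES}")
        beta = {"FS1": 1.0, "FS05": 0.5}.get(self.name, self.beta)
        object.__setattr__(self, "beta", beta)
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")


# -- fold generation -----------------------------------------------------------


def generate_rejection_folds(
    train: LabeledExpressionDataset, m: int = 10, x: int = 1, seed: int = 0
) -> list[FoldSpec]:
    """k·m folds, iterating the held-out (reject-playing) class over all k.

    Within a fold, test samples are drawn without replacement: x per remaining
    class (targets) and x from the held-out class (rejects); the fold's
    training set is the remaining classes' samples minus its test targets.
    Requires k >= 3 classes (so the reduced target set keeps >= 2 classes) and
    every class strictly larger than x.
    """
    if m < 1 or x < 1:
        raise ConfigurationError("m and x must be >= 1")
    classes = train.classes
    if len(classes) < 3:
        raise ConfigurationError(
            f"need at least 3 classes for leave-one-class-out folds, got {len(classes)}"
        )
    by_class = {c: [s for s, l in zip(train.sample_ids, train.labels) if l == c] for c in classes}
    for c, ids in by_class.items():
        if len(ids) <= x:
            raise ConfigurationError(
                f"class {c!r} has {len(ids)} samples, need more than x={x}"
            )
    rng = np.random.default_rng(seed)
    folds: list[FoldSpec] = []
    for held_out in classes:
        others = [c for c in classes if c != held_out]
        for j in range(m):
            test_target: list[str] = []
            for c in others:
                pick = rng.choice(len(by_class[c]), size=x, replace=False)
                test_target.extend(by_class[c][i] for i in pick)
            pick_r = rng.choice(len(by_class[held_out]), size=x, replace=False)
            test_reject = [by_class[held_out][i] for i in pick_r]
            removed = set(test_target)
            train_ids = [
                s for c in others for s in by_class[c] if s not in removed
            ]
            folds.append(
                FoldSpec(
                    held_out_class=held_out,
                    fold_index=j,
                    train_sample_ids=tuple(train_ids),
                    test_target_ids=tuple(test_target),
                    test_reject_ids=tuple(test_reject),
                )
            )
    return folds


def collect_tuning_sample(
    train: LabeledExpressionDataset,
    folds: Sequence[FoldSpec],
    train_config: TrainConfig,
    variance_retained: float = 0.95,
    freq_cut: float = 95 / 5,
    unique_cut: float = 10.0,
) -> TuningSample:
    """Run each fold's independent classification experiment and harvest
    (max1, max2, is_target) for every fold test sample.

    Preprocessing and the classifier are fitted on the fold's Train* only;
    a sample is a target record iff its label differs from the fold's
    held-out class.
    """
    records: list[TuningRecord] = []
    for fold in folds:
        try:
            tr = train.subset_by_ids(fold.train_sample_ids)
            te_ids = list(fold.test_target_ids) + list(fold.test_reject_ids)
            te = train.subset_by_ids(te_ids)
            pre = fit_preprocessor(tr, variance_retained, freq_cut, unique_cut)
            Xtr = apply_preprocessor(pre, tr)
            Xte = apply_preprocessor(pre, te)
            model = train_probabilistic_classifier(Xtr, tr.labels, train_config)
            probs = predict_class_probabilities(model, Xte, te.sample_ids)
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise ConfigurationError(
                f"fold (class {fold.held_out_class!r}, index {fold.fold_index}) failed: {exc}"
            ) from exc
        for row, label in zip(probs.probs, te.labels):
            tt = top_two(row, probs.class_ids)
            records.append(
                TuningRecord(
                    max1=tt.max1,
                    max2=tt.max2,
                    is_target=(label != fold.held_out_class),
                    fold=fold,
                )
            )
    return TuningSample(records=records)


# -- objectives ----------------------------------------------------------------


def confusion_from_records(
    max1: np.ndarray, max2: np.ndarray, is_target: np.ndarray, triple: np.ndarray
) -> ConfusionSummary:
    """Vectorized rule application over (max1, max2) records for one
    (t_max, t_rej, t_diff) triple; mirrors :func:`rejectlearn.rejection.decide`."""
    t_max, t_rej, t_diff = float(triple[0]), float(triple[1]), float(triple[2])
    r1 = max1 < t_rej
    r2 = ~r1 & (max1 > t_max)
    r31 = ~r1 & ~r2 & ((max1 - max2) > t_diff)
    r32 = ~r1 & ~r2 & ~r31 & (max2 > t_rej)
    accept = r2 | r31
    uncertain = r32
    reject = ~accept & ~uncertain
    return ConfusionSummary(
        tp=int(np.sum(accept & is_target)),
        fp=int(np.sum(accept & ~is_target)),
        tn=int(np.sum(reject & ~is_target)),
        fn=int(np.sum(reject & is_target)),
        unc_target=int(np.sum(uncertain & is_target)),
        unc_reject=int(np.sum(uncertain & ~is_target)),
    )


def objective_value(spec: ObjectiveSpec, confusion: ConfusionSummary) -> float:
    """Evaluate one tuning objective on a confusion summary (lower is better;
    0 iff discrimination is perfect)."""
    if confusion.n_targets == 0 or confusion.n_rejects == 0:
        raise ConfigurationError("objective needs both target and reject samples")
    sens = confusion.tp / confusion.n_targets
    spec_rate = confusion.tn / confusion.n_rejects
    if spec.name == "SS":
        return (1 - sens) + (1 - spec_rate)
    if spec.name == "SS1":
        return (1 - sens) ** 2 + (1 - spec_rate) ** 2
    if spec.name == "SS2":
        return max(1 - sens, 1 - spec_rate)
    # F-score objectives: precision over accepted, recall = sensitivity
    denom = confusion.tp + confusion.fp
    p = confusion.tp / denom if denom else 0.0
    r = sens
    b2 = spec.beta**2
    if p + r == 0:
        return 1.0
    return 1.0 - (1 + b2) * p * r / (b2 * p + r)


# -- CMA-ES threshold optimization ---------------------------------------------

_PENALTY_BASE = 2.0  # exceeds every feasible objective value (SS max is 2)


def _threshold_objective(sample: TuningSample, spec: ObjectiveSpec):
    max1, max2, is_target = sample.arrays()

    def f(v: np.ndarray) -> float:
        t_max, t_rej, t_diff = float(v[0]), float(v[1]), float(v[2])
        violation = 0.0
        for t in (t_max, t_rej, t_diff):
            violation += max(0.0, -t) + max(0.0, t - 1.0)
        if t_rej >= t_max:
            violation += (t_rej - t_max) + 1e-9
        if violation > 0:
            return _PENALTY_BASE + violation
        return objective_value(
            spec, confusion_from_records(max1, max2, is_target, v)
        )

    return f


def optimize_thresholds(
    sample: TuningSample,
    spec: ObjectiveSpec = ObjectiveSpec("SS1"),
    config: CMAESConfig | None = None,
    max_restarts: int = 3,
    restart_above: float = 0.2,
) -> tuple[RejectionThresholds, float]:
    """Minimize the tuning objective over (T_max, T_rej, T_diff) by CMA-ES.

    If a run terminates on a stall criterion while the best value is still
    above ``restart_above``, the search restarts with a doubled population
    (up to ``max_restarts`` times) — the standard remedy for premature
    convergence of small CMA-ES populations.  Returns the best feasible
    thresholds and the tuning-sample objective value recomputed at them.
    """
    if config is None:
        config = CMAESConfig()
    f = _threshold_objective(sample, spec)
    result = cmaes_minimize(f, config)
    best = result
    lam = config.population_size or 7  # 4 + floor(3 ln 3)
    restarts = 0
    while (
        result.stop_reason in ("stall_delta", "long_stall")
        and best.best_f > restart_above
        and restarts < max_restarts
    ):
        lam *= 2
        restarts += 1
        rcfg = replace(
            config,
            population_size=lam,
            seed=(config.seed + 9973 * restarts) % (2**31 - 1),
        )
        result = cmaes_minimize(f, rcfg)
        if result.best_f < best.best_f:
            best = result
    v = best.best_x
    thresholds = RejectionThresholds(
        t_max=float(min(max(v[0], 0.0), 1.0)),
        t_rej=float(min(max(v[1], 0.0), 1.0)),
        t_diff=float(min(max(v[2], 0.0), 1.0)),
    )
    max1, max2, is_target = sample.arrays()
    achieved = objective_value(
        spec, confusion_from_records(max1, max2, is_target, thresholds.as_vector())
    )
    return thresholds, achieved
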