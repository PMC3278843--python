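"""Confusion accounting, rates, confidence intervals, ROC and experiment groups.

The reject option is evaluated as a binary test over *target* samples (truly
belonging to a trained class) and *reject* samples (belonging to none):

* TP — target accepted, TN — reject rejected,
* FP — reject accepted, FN — target rejected,
* plus *uncertain* outcomes, counted separately per true side.

Sensitivity keeps uncertain targets in its denominator and specificity keeps
uncertain rejects in its denominator: abstaining is a failure to accept (or
reject) correctly, just not a misclassification.  Whether a sample was
assigned the *right* class when accepted is outside this accounting — that is
the multi-class classifier's job, not the rejector's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ConfigurationError, LabeledExpressionDataset
from .rejection import Decision, Outcome, RejectionThresholds

__all__ = [
    "ConfusionSummary",
    "RateSet",
    "ROCPointSet",
    "tally_confusion",
    "binary_rates",
    "mean_confidence_interval",
    "roc_points_rules",
    "roc_points_one_class",
    "ExperimentGroupResult",
    "run_experiment_group",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/TN/FP/FN plus uncertain counts split by the true side."""

    tp: int
    tn: int
    fp: int
    fn: int
    unc_target: int = 0
    unc_reject: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "unc_target", "unc_reject"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"count {name} must be >= 0")

    @property
    def n_targets(self) -> int:
        return self.tp + self.fn + self.unc_target

    @property
    def n_rejects(self) -> int:
        return self.tn + self.fp + self.unc_reject

    @property
    def total(self) -> int:
        return self.n_targets + self.n_rejects


@dataclass(frozen=True)
class RateSet:
    sens: float
    spec: float
    precision: float
    recall: float
    accuracy: float

    def __post_init__(self) -> None:
        for name in ("sens", "spec", "precision", "recall", "accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"rate {name}={v} outside [0, 1]")


def tally_confusion(
    decisions: Sequence[Decision], truth: Sequence[bool]
) -> ConfusionSummary:
    """Count outcomes against per-sample is-target flags.

    Acceptance of a true target counts as TP regardless of which class label
    was assigned.
    """
    if len(decisions) != len(truth):
        raise ConfigurationError("decisions and truth must have equal length")
    tp = tn = fp = fn = ut = ur = 0
    for d, is_target in zip(decisions, truth):
        if d.outcome is Outcome.ACCEPT:
            if is_target:
                tp += 1
            else:
                fp += 1
        elif d.outcome is Outcome.REJECT:
            if is_target:
                fn += 1
            else:
                tn += 1
        else:
            if is_target:
                ut += 1
            else:
                ur += 1
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn, unc_target=ut, unc_reject=ur)


def binary_rates(
    confusion: ConfusionSummary, include_uncertain_in_accuracy: bool = True
) -> RateSet:
    """Sensitivity/specificity/precision/recall/accuracy with uncertain outcomes.

    sens = TP / (TP + FN + uncertain targets); spec = TN / (TN + FP +
    uncertain rejects); precision = TP / (TP + FP) (0 when nothing accepted);
    accuracy = (TP + TN) / total, with the uncertain samples included in the
    denominator by default (``include_uncertain_in_accuracy=False`` drops
    them, reading "classified samples" as the non-abstained ones).
    """
    if confusion.n_targets == 0 or confusion.n_rejects == 0:
        raise ConfigurationError("rates need at least one target and one reject sample")
    sens = confusion.tp / confusion.n_targets
    spec = confusion.tn / confusion.n_rejects
    denom = confusion.tp + confusion.fp
    precision = confusion.tp / denom if denom else 0.0
    acc_denom = (
        confusion.total
        if include_uncertain_in_accuracy
        else confusion.tp + confusion.tn + confusion.fp + confusion.fn
    )
    accuracy = (confusion.tp + confusion.tn) / acc_denom if acc_denom else 0.0
    return RateSet(sens=sens, spec=spec, precision=precision, recall=sens, accuracy=accuracy)


def mean_confidence_interval(
    values: Sequence[float],
    level: float = 0.95,
    clip: tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """Normal-approximation interval mean ± z·sd/√n (sd with n−1 denominator).

    ``clip`` bounds the interval (e.g. (0, 1) for rates).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ConfigurationError("need at least 2 values for a confidence interval")
    if not (0 < level < 1):
        raise ConfigurationError("level must lie in (0, 1)")
    mean = float(x.mean())
    half = float(stats.norm.ppf((1 + level) / 2) * x.std(ddof=1) / np.sqrt(x.size))
    lo, hi = mean - half, mean + half
    if clip is not None:
        lo, hi = max(lo, clip[0]), min(hi, clip[1])
    return mean, lo, hi


# -- ROC construction ----------------------------------------------------------


@dataclass(frozen=True)
class ROCPointSet:
    """(FPR, TPR) points with the parameter that produced each one."""

    points: list[tuple[float, float, object]]

    def __post_init__(self) -> None:
        if not self.points:
            raise ConfigurationError("ROC point set must be nonempty")
        for fpr, tpr, _ in self.points:
            if not (0 <= fpr <= 1 and 0 <= tpr <= 1):
                raise ConfigurationError("ROC rates must lie in [0, 1]")

    def staircase(self) -> list[tuple[float, float]]:
        """Upper-left Pareto envelope, monotone non-decreasing in TPR."""
        pts = sorted((fpr, tpr) for fpr, tpr, _ in self.points)
        out: list[tuple[float, float]] = []
        best = -1.0
        for fpr, tpr in pts:
            if tpr > best:
                out.append((fpr, tpr))
                best = tpr
        return out


def _rates_from_counts(max1, max2, is_target, triple):
    from .tuning import confusion_from_records  # local: avoids import cycle

    c = confusion_from_records(max1, max2, is_target, triple)
    if c.n_rejects == 0 or c.n_targets == 0:
        raise ConfigurationError("ROC needs both target and reject samples")
    # uncertain counts as non-acceptance on both axes
    return c.fp / c.n_rejects, c.tp / c.n_targets


def roc_points_rules(
    max1: np.ndarray,
    max2: np.ndarray,
    is_target: np.ndarray,
    n_triples: int = 2000,
    seed: int = 0,
    extra_triples: Sequence[RejectionThresholds] = (),
) -> ROCPointSet:
    """ROC sweep of the rule engine over quasi-random valid threshold triples.

    Scrambled-Sobol points fill the (T_rej < T_max, T_diff) space; degenerate
    accept-everything and reject-everything triples anchor the (1,1) and
    (0,0) endpoints.  UNCERTAIN counts as non-acceptance.
    """
    sob = stats.qmc.Sobol(d=3, scramble=True, rng=seed)
    u = sob.random(n_triples)
    pts: list[tuple[float, float, object]] = []
    eps = 1e-9
    anchors = [
        RejectionThresholds(t_max=eps, t_rej=0.0, t_diff=0.0),      # accept everything
        RejectionThresholds(t_max=1.0, t_rej=1.0 - eps, t_diff=1.0) # reject everything
    ]
    for trip in anchors + list(extra_triples):
        fpr, tpr = _rates_from_counts(max1, max2, is_target, trip.as_vector())
        pts.append((fpr, tpr, trip))
    for row in u:
        lo, hi = sorted(row[:2])
        if hi <= lo:
            hi = lo + eps
        trip = RejectionThresholds(t_max=min(hi, 1.0), t_rej=max(lo, 0.0), t_diff=float(row[2]))
        fpr, tpr = _rates_from_counts(max1, max2, is_target, trip.as_vector())
        pts.append((fpr, tpr, trip))
    return ROCPointSet(points=pts)


def roc_points_one_class(
    train_scores: np.ndarray,
    test_scores: np.ndarray,
    is_target: np.ndarray,
    rates: Sequence[float] | None = None,
) -> ROCPointSet:
    """ROC sweep of a one-class scorer by varying the training rejection rate.

    For each rate the acceptance threshold is re-set to the (1 − rate)
    empirical quantile of the training scores.
    """
    if rates is None:
        rates = np.linspace(0.0, 0.99, 100)
    is_target = np.asarray(is_target, dtype=bool)
    n_t = int(is_target.sum())
    n_r = int((~is_target).sum())
    if n_t == 0 or n_r == 0:
        raise ConfigurationError("ROC needs both target and reject samples")
    pts = []
    for rate in rates:
        thr = float(np.quantile(train_scores, 1 - rate))
        accept = np.asarray(test_scores) <= thr
        tpr = float(accept[is_target].sum() / n_t)
        fpr = float(accept[~is_target].sum() / n_r)
        pts.append((fpr, tpr, float(rate)))
    # endpoints: reject everything / accept everything
    pts.append((0.0, 0.0, "reject_all"))
    pts.append((1.0, 1.0, "accept_all"))
    return ROCPointSet(points=pts)


# -- experiment groups ----------------------------------------------------------


@dataclass
class ExperimentGroupResult:
    """Aggregated comparison of rule-based rejection against baselines."""

    summary: pd.DataFrame          # one row per method: rates with CIs
    per_experiment: pd.DataFrame   # one row per (experiment, method)
    achieved_objectives: list[float]  # tuning objective value per experiment


def run_experiment_group(
    dataset: LabeledExpressionDataset,
    k_target: int,
    n_experiments: int,
    algorithms: Sequence[str] = ("rf",),
    baselines: Sequence[str] = (),
    baseline_modes: Sequence[str] = ("socmt",),
    train_fraction: float = 0.7,
    m_folds: int = 5,
    x_per_class: int = 1,
    objective: str = "SS1",
    variance_retained: float = 0.95,
    train_config=None,
    rejection_rate: float = 0.1,
    seed: int = 0,
    confidence_level: float = 0.95,
) -> ExperimentGroupResult:
    """The G_k design: k target phenotypes, the rest must be rejected.

    Each experiment draws a random ``k_target``-class target panel, splits the
    panel's samples into training and test-target pools, balances the test set
    (equal target and reject counts by downsampling the larger side), tunes
    thresholds on the training data only via leave-one-class-out folds, and
    evaluates the rule-based rejector and the requested one-class baselines on
    the same test set.  Returns per-method mean sens/spec/accuracy with
    confidence intervals, plus the achieved tuning objective per experiment
    (the reliability indicator: 0 means perfect discrimination on the tuning
    sample).
    """
    from . import oneclass as oc
    from . import tuning as tn
    from .classifiers import TrainConfig, predict_class_probabilities, train_probabilistic_classifier
    from .preprocess import apply_preprocessor, fit_preprocessor
    from .rejection import classify_with_rejection

    classes = dataset.classes
    if len(classes) <= k_target:
        raise ConfigurationError("dataset must have more classes than k_target")
    if k_target < 3:
        raise ConfigurationError("k_target must be >= 3 for leave-one-class-out tuning")
    if train_config is None:
        train_config = TrainConfig(algorithm="rf", n_candidates=1, resampling_repeats=1)

    rng = np.random.default_rng(seed)
    rows = []
    objectives: list[float] = []
    for e in range(n_experiments):
        exp_seed = int(rng.integers(0, 2**31 - 1))
        exp_rng = np.random.default_rng(exp_seed)
        panel = list(exp_rng.choice(np.asarray(classes, dtype=object), size=k_target, replace=False))

        # split target-class samples into train / test-target pools
        train_idx: list[int] = []
        test_target_idx: list[int] = []
        for c in panel:
            idx = dataset.indices_of_labels([c])
            idx = exp_rng.permutation(idx)
            n_tr = max(2, int(round(train_fraction * idx.size)))
            n_tr = min(n_tr, idx.size - 1)
            train_idx.extend(idx[:n_tr].tolist())
            test_target_idx.extend(idx[n_tr:].tolist())
        reject_idx = dataset.indices_of_labels([c for c in classes if c not in panel])

        # balanced test set
        n_bal = min(len(test_target_idx), len(reject_idx))
        if n_bal == 0:
            raise ConfigurationError("not enough samples to balance the test set")
        test_t = exp_rng.choice(np.asarray(test_target_idx), size=n_bal, replace=False)
        test_r = exp_rng.choice(np.asarray(reject_idx), size=n_bal, replace=False)
        train_ds = dataset.subset(sorted(train_idx))
        test_ds = dataset.subset(np.concatenate([np.sort(test_t), np.sort(test_r)]))
        truth = [l in panel for l in test_ds.labels]

        pre = fit_preprocessor(train_ds, variance_retained=variance_retained)
        Xtr = apply_preprocessor(pre, train_ds)
        Xte = apply_preprocessor(pre, test_ds)

        # rule-based methods
        folds = tn.generate_rejection_folds(train_ds, m=m_folds, x=x_per_class, seed=exp_seed)
        for algo in algorithms:
            cfg = TrainConfig(
                algorithm=algo,
                n_candidates=train_config.n_candidates,
                resampling_repeats=train_config.resampling_repeats,
                train_fraction=train_config.train_fraction,
                n_trees=train_config.n_trees,
                seed=exp_seed,
            )
            sample = tn.collect_tuning_sample(
                train_ds, folds, cfg, variance_retained=variance_retained
            )
            thresholds, achieved = tn.optimize_thresholds(
                sample,
                tn.ObjectiveSpec(name=objective),
                tn.CMAESConfig(seed=exp_seed),
            )
            if algo == algorithms[0]:
                objectives.append(achieved)
            clf = train_probabilistic_classifier(Xtr, train_ds.labels, cfg)
            probs = predict_class_probabilities(clf, Xte, test_ds.sample_ids)
            decisions = classify_with_rejection(probs, thresholds)
            rates = binary_rates(tally_confusion(decisions, truth))
            rows.append(
                dict(experiment=e, method=f"{algo}+rule", sens=rates.sens,
                     spec=rates.spec, accuracy=rates.accuracy, objective=achieved)
            )

        # one-class baselines on the same transformed space
        sub_labels = np.asarray(train_ds.labels, dtype=object)
        for method in baselines:
            for mode in baseline_modes:
                if mode == "socmt":
                    model = oc.fit_one_class(
                        Xtr, method, rejection_rate=rejection_rate, seed=exp_seed
                    )
                    ensemble = oc.OneClassEnsemble(mode="SOCMT", models=[model])
                    accept = oc.predict_socmt(ensemble, Xte)
                else:
                    models = [
                        oc.fit_one_class(
                            Xtr[sub_labels == c], method,
                            rejection_rate=rejection_rate, seed=exp_seed,
                        )
                        for c in panel
                    ]
                    ensemble = oc.OneClassEnsemble(mode="MOCV", models=models)
                    accept = oc.predict_mocv(ensemble, Xte)
                conf = ConfusionSummary(
                    tp=int(np.sum(accept & np.asarray(truth))),
                    fp=int(np.sum(accept & ~np.asarray(truth))),
                    fn=int(np.sum(~accept & np.asarray(truth))),
                    tn=int(np.sum(~accept & ~np.asarray(truth))),
                )
                rates = binary_rates(conf)
                rows.append(
                    dict(experiment=e, method=f"{method}-{mode}", sens=rates.sens,
                         spec=rates.spec, accuracy=rates.accuracy, objective=np.nan)
                )

    per_exp = pd.DataFrame(rows)
    summary_rows = []
    for method, grp in per_exp.groupby("method", sort=False):
        entry = {"method": method}
        for col in ("sens", "spec", "accuracy"):
            vals = grp[col].to_numpy()
            if vals.size >= 2:
                mean, lo, hi = mean_confidence_interval(vals, confidence_level, clip=(0, 1))
            else:
                mean, lo, hi = float(vals[0]), float(vals[0]), float(vals[0])
            entry[col] = mean
            entry[f"{col}_lo"] = lo
            entry[f"{col}_hi"] = hi
        summary_rows.append(entry)
    return ExperimentGroupResult(
        summary=pd.DataFrame(summary_rows),
        per_experiment=per_exp,
        achieved_objectives=objectives,
    )
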