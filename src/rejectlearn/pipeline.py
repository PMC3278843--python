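"""End-to-end pipeline: preprocess → train → tune thresholds → decide → report.

The pipeline reproduces the full flow for setting up a multi-class classifier
with a rejection option: fit preprocessing on the training set, train the
probabilistic classifier, harvest a tuning sample via leave-one-class-out
folds, optimize the three thresholds by CMA-ES, apply the decision rules to
the test set, and write a small evaluation report.  Every artifact is
accompanied by a manifest recording the configuration hash and the global
seed, and a rerun with an identical configuration reproduces identical
outputs.  The single global seed fans out to per-stage seeds through a fixed
stage-name hash so stages stay independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .classifiers import TrainConfig, predict_class_probabilities, train_probabilistic_classifier
from .data import ConfigurationError
from .evaluation import binary_rates, tally_confusion
from .preprocess import apply_preprocessor, fit_preprocessor
from .rejection import classify_with_rejection
from .tuning import CMAESConfig, ObjectiveSpec, collect_tuning_sample, generate_rejection_folds, optimize_thresholds

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    h = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    train_path: str
    output_dir: str
    test_path: str | None = None
    target_classes: list[str] | None = None   # labels counted as targets in the report
    algorithm: str = "rf"
    n_candidates: int = 1
    resampling_repeats: int = 1
    train_fraction: float = 0.98
    n_trees: int = 500
    variance_retained: float = 0.95
    m_folds: int = 10
    x_per_class: int = 1
    objective: str = "SS1"
    cmaes_max_generations: int = 500
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    thresholds_path: Path
    decisions_path: Path | None
    report_path: Path | None
    manifest_path: Path
    achieved_objective: float


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full flow; halts at the first failing stage with its name."""
    out = Path(config.output_dir)
    train_path = Path(config.train_path)
    if not train_path.exists():
        raise ConfigurationError(f"[config] training file not found: {train_path}")
    if config.test_path is not None and not Path(config.test_path).exists():
        raise ConfigurationError(f"[config] test file not found: {config.test_path}")
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    train_ds = stage("load")(rio.read_expression_csv, train_path)
    pre = stage("preprocess")(
        fit_preprocessor, train_ds, variance_retained=config.variance_retained
    )
    Xtr = apply_preprocessor(pre, train_ds)
    tcfg = TrainConfig(
        algorithm=config.algorithm,
        n_candidates=config.n_candidates,
        resampling_repeats=config.resampling_repeats,
        train_fraction=config.train_fraction,
        n_trees=config.n_trees,
        seed=stage_seed(config.seed, "train"),
    )
    model = stage("train")(train_probabilistic_classifier, Xtr, train_ds.labels, tcfg)

    folds = stage("folds")(
        generate_rejection_folds,
        train_ds,
        m=config.m_folds,
        x=config.x_per_class,
        seed=stage_seed(config.seed, "folds"),
    )
    sample = stage("tuning-sample")(
        collect_tuning_sample, train_ds, folds, tcfg,
        variance_retained=config.variance_retained,
    )
    thresholds, achieved = stage("optimize")(
        optimize_thresholds,
        sample,
        ObjectiveSpec(name=config.objective),
        CMAESConfig(
            seed=stage_seed(config.seed, "cmaes"),
            max_generations=config.cmaes_max_generations,
        ),
    )

    thresholds_path = out / "thresholds.json"
    rio.write_thresholds_json(thresholds, thresholds_path)
    pre.to_json(out / "preprocess.json")
    model.save(out / "model.joblib")
    rio.write_tuning_sample_csv(sample, out / "tuning_sample.csv")

    decisions_path = report_path = None
    if config.test_path is not None:
        test_ds = stage("load-test")(rio.read_expression_csv, config.test_path)
        Xte = apply_preprocessor(pre, test_ds)
        probs = stage("predict")(
            predict_class_probabilities, model, Xte, test_ds.sample_ids
        )
        decisions = classify_with_rejection(probs, thresholds)
        decisions_path = out / "decisions.csv"
        rio.write_decisions_csv(decisions, probs, decisions_path)
        target_set = set(config.target_classes or train_ds.classes)
        truth = [l in target_set for l in test_ds.labels]
        report_path = out / "report.csv"
        if any(truth) and not all(truth):
            rates = binary_rates(tally_confusion(decisions, truth))
            with open(report_path, "w") as fh:
                fh.write("metric,value\n")
                for k in ("sens", "spec", "precision", "recall", "accuracy"):
                    fh.write(f"{k},{getattr(rates, k):.12g}\n")
                fh.write(f"tuning_objective,{achieved:.12g}\n")
        else:
            report_path = None

    manifest_path = out / "manifest.json"
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": asdict(config),
        "achieved_objective": achieved,
        "thresholds": {
            "t_max": thresholds.t_max,
            "t_rej": thresholds.t_rej,
            "t_diff": thresholds.t_diff,
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        thresholds_path=thresholds_path,
        decisions_path=decisions_path,
        report_path=report_path,
        manifest_path=manifest_path,
        achieved_objective=achieved,
    )
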