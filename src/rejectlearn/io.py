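"""Readers and writers for the package's delimited-text artifacts.

Expression matrices travel as CSV/TSV with one row per sample: first column
the sample id, second the phenotype label, remaining columns the gene values
under a header row of gene ids.  Probability matrices, decisions, tuning
samples and results tables are plain CSV; thresholds are a 3-field JSON
document.  Values are written with 12 significant digits so round-trips are
lossless at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import ProbEstimateMatrix
from .data import ConfigurationError, LabeledExpressionDataset
from .rejection import Decision, RejectionThresholds, top_two
from .tuning import TuningRecord, TuningSample

__all__ = [
    "write_expression_csv",
    "read_expression_csv",
    "write_prob_matrix_csv",
    "read_prob_matrix_csv",
    "write_thresholds_json",
    "read_thresholds_json",
    "write_decisions_csv",
    "write_tuning_sample_csv",
    "read_tuning_sample_csv",
]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_expression_csv(dataset: LabeledExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(dataset.values, columns=dataset.gene_ids)
    df.insert(0, "label", dataset.labels)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.12g")


def read_expression_csv(path: str | Path) -> LabeledExpressionDataset:
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "label"]:
        raise ConfigurationError(
            "expression file must start with 'sample_id' and 'label' columns"
        )
    return LabeledExpressionDataset(
        values=df.iloc[:, 2:].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
        gene_ids=[str(c) for c in df.columns[2:]],
        labels=df["label"].astype(str).tolist(),
    )


def write_prob_matrix_csv(probs: ProbEstimateMatrix, path: str | Path) -> None:
    df = pd.DataFrame(probs.probs, columns=probs.class_ids)
    df.insert(0, "sample_id", probs.sample_ids)
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.12g")


def read_prob_matrix_csv(path: str | Path) -> ProbEstimateMatrix:
    df = pd.read_csv(path, sep=_sep(path))
    if df.columns[0] != "sample_id":
        raise ConfigurationError("probability file must start with 'sample_id'")
    return ProbEstimateMatrix(
        class_ids=[str(c) for c in df.columns[1:]],
        probs=df.iloc[:, 1:].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def write_thresholds_json(thresholds: RejectionThresholds, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"t_max": thresholds.t_max, "t_rej": thresholds.t_rej, "t_diff": thresholds.t_diff},
            indent=2,
        )
        + "\n"
    )


def read_thresholds_json(path: str | Path) -> RejectionThresholds:
    doc = json.loads(Path(path).read_text())
    return RejectionThresholds(
        t_max=float(doc["t_max"]), t_rej=float(doc["t_rej"]), t_diff=float(doc["t_diff"])
    )


def write_decisions_csv(
    decisions: Sequence[Decision],
    probs: ProbEstimateMatrix,
    path: str | Path,
) -> None:
    """Per-sample decisions with the rule that fired and the top-two estimates."""
    rows = []
    for sid, d, row in zip(probs.sample_ids, decisions, probs.probs):
        tt = top_two(row, probs.class_ids)
        rows.append(
            dict(
                sample_id=sid,
                outcome=d.outcome.value,
                assigned_class=d.assigned_class if d.assigned_class is not None else "",
                rule_fired=d.rule_fired.value,
                max1=tt.max1,
                max2=tt.max2,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False, float_format="%.12g")


def write_tuning_sample_csv(sample: TuningSample, path: str | Path) -> None:
    rows = [
        dict(
            max1=r.max1,
            max2=r.max2,
            is_target=int(r.is_target),
            fold_id=(
                f"{r.fold.held_out_class}:{r.fold.fold_index}" if r.fold is not None else ""
            ),
        )
        for r in sample.records
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False, float_format="%.12g")


def read_tuning_sample_csv(path: str | Path) -> TuningSample:
    df = pd.read_csv(path, sep=_sep(path))
    records = [
        TuningRecord(max1=float(r.max1), max2=float(r.max2), is_target=bool(r.is_target))
        for r in df.itertuples()
    ]
    return TuningSample(records=records)
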