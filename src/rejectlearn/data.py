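"""Labeled expression-matrix container.

The raw-input role of the whole package: a samples × genes matrix of
log-ratio expression values (log2 of the two-channel ratio of a cDNA
array, or any comparable continuous measurement) together with one
phenotype label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a configuration or container violates a stated invariant."""


@dataclass
class LabeledExpressionDataset:
    """Samples × genes log-ratio matrix with per-sample phenotype labels.

    Invariants (enforced at construction):

    * ``values.shape == (len(sample_ids), len(gene_ids))``
    * ``len(labels) == len(sample_ids)``
    * all values finite
    * at least two distinct labels
    * sample and gene identifiers unique
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(l) for l in self.labels]
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-D samples × genes matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ConfigurationError(
                f"row count {n} != number of sample ids {len(self.sample_ids)}"
            )
        if n != len(self.labels):
            raise ConfigurationError(
                f"row count {n} != number of labels {len(self.labels)}"
            )
        if p != len(self.gene_ids):
            raise ConfigurationError(
                f"column count {p} != number of gene ids {len(self.gene_ids)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("expression values must all be finite")
        if len(set(self.sample_ids)) != n:
            raise ConfigurationError("sample ids must be unique")
        if len(set(self.gene_ids)) != p:
            raise ConfigurationError("gene ids must be unique")
        if len(set(self.labels)) < 2:
            raise ConfigurationError("dataset must contain at least 2 distinct labels")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l, None)
        return list(seen)

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledExpressionDataset":
        """Row subset by positional indices (order preserved, no validation relax).

        The subset may end up with a single label; that is permitted here because
        per-class slices are legitimate intermediates (e.g. one-class training),
        so the two-label invariant is not re-imposed.
        """
        idx = np.asarray(indices, dtype=int)
        ds = object.__new__(LabeledExpressionDataset)
        ds.values = self.values[idx]
        ds.sample_ids = [self.sample_ids[i] for i in idx]
        ds.gene_ids = list(self.gene_ids)
        ds.labels = [self.labels[i] for i in idx]
        return ds

    def subset_by_ids(self, ids: Iterable[str]) -> "LabeledExpressionDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return self.subset([pos[s] for s in ids])

    def indices_of_labels(self, labels: Iterable[str]) -> np.ndarray:
        want = set(labels)
        return np.array([i for i, l in enumerate(self.labels) if l in want], dtype=int)
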