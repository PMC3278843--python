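"""Synthetic data generators.

Two generators make every downstream stage testable without external data:

* :func:`generate_expression_dataset` emulates the structure of multi-
  phenotype expression studies — many genes, few samples per class, and only
  a small dedicated subset of genes discriminating each class.  Background
  values are i.i.d. Gaussian log-ratio noise; each class's informative genes
  receive an additive mean shift for that class's samples.

* :func:`sample_tuning_distribution` draws (max1, max2) top-two probability
  records directly from bounded Beta distributions, emulating the empirical
  MAX/DIFF shapes: confident, well-margined estimates for target samples and
  low, near-tied estimates for reject samples.  max2 is generated as a
  fraction of min(max1, 1 − max1), which guarantees the probability geometry
  max2 <= max1 and max1 + max2 <= 1 by construction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .data import ConfigurationError, LabeledExpressionDataset
from .tuning import TuningRecord, TuningSample

__all__ = [
    "SynthConfig",
    "BetaParams",
    "TuningDistributionConfig",
    "generate_expression_dataset",
    "split_target_reject",
    "sample_tuning_distribution",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shape and signal parameters of a synthetic expression dataset.

    Defaults emulate a several-phenotype study: 7 classes of 20 samples over
    1000 genes with 20 dedicated informative genes per class, a 2.0 log-ratio
    mean shift on them, and unit-variance background noise.
    """

    n_classes: int = 7
    samples_per_class: int = 20
    n_genes: int = 1000
    n_informative_per_class: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.samples_per_class < 1:
            raise ConfigurationError("samples_per_class must be >= 1")
        if self.n_informative_per_class < 0:
            raise ConfigurationError("n_informative_per_class must be >= 0")
        if self.n_informative_per_class * self.n_classes > self.n_genes:
            raise ConfigurationError(
                "n_informative_per_class * n_classes must not exceed n_genes"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


def _class_names(k: int) -> list[str]:
    if k <= 26:
        return list(string.ascii_uppercase[:k])
    return [f"C{i:03d}" for i in range(k)]


def generate_expression_dataset(config: SynthConfig) -> LabeledExpressionDataset:
    """Draw a labeled log-ratio matrix; deterministic for a fixed seed.

    Gene block ``c*n_inf : (c+1)*n_inf`` is the informative set of class c:
    its entries are shifted by ``effect_size`` for that class's samples only.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_classes * config.samples_per_class
    values = rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))
    names = _class_names(config.n_classes)
    labels = [names[c] for c in range(config.n_classes) for _ in range(config.samples_per_class)]
    ni = config.n_informative_per_class
    for c in range(config.n_classes):
        rows = slice(c * config.samples_per_class, (c + 1) * config.samples_per_class)
        cols = slice(c * ni, (c + 1) * ni)
        values[rows, cols] += config.effect_size
    return LabeledExpressionDataset(
        values=values,
        sample_ids=[f"S{i:04d}" for i in range(n)],
        gene_ids=[f"G{j:05d}" for j in range(config.n_genes)],
        labels=labels,
    )


def split_target_reject(
    dataset: LabeledExpressionDataset, target_classes
) -> tuple[LabeledExpressionDataset, LabeledExpressionDataset]:
    """Partition samples into a target subset (labels in ``target_classes``)
    and a reject subset (every other label)."""
    target = set(str(c) for c in target_classes)
    present = set(dataset.labels)
    if not target:
        raise ConfigurationError("target_classes must be nonempty")
    unknown = target - present
    if unknown:
        raise ConfigurationError(f"unknown target classes: {sorted(unknown)}")
    if target == present:
        raise ConfigurationError(
            "target_classes equals all labels; no reject class remains"
        )
    t_idx = [i for i, l in enumerate(dataset.labels) if l in target]
    r_idx = [i for i, l in enumerate(dataset.labels) if l not in target]
    return dataset.subset(t_idx), dataset.subset(r_idx)


@dataclass(frozen=True)
class BetaParams:
    """A Beta(a, b) distribution affinely mapped to [loc, loc + scale] ⊆ [0, 1]."""

    a: float
    b: float
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("Beta shape parameters must be positive")
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        if self.loc < 0 or self.loc + self.scale > 1 + 1e-12:
            raise ConfigurationError(
                "distribution support must lie within [0, 1]: "
                f"[{self.loc}, {self.loc + self.scale}]"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.loc + self.scale * rng.beta(self.a, self.b, size=n)


@dataclass(frozen=True)
class TuningDistributionConfig:
    """Direct (max1, max2) record generator parameters.

    ``*_max1_params`` drive the top estimate; ``*_diff_params`` drive the
    fraction g of min(max1, 1 − max1) assigned to max2 — small fractions mean
    large margins (targets), fractions near 1 mean near-ties (rejects).
    """

    n_target: int = 200
    n_reject: int = 200
    target_max1_params: BetaParams = field(default_factory=lambda: BetaParams(8, 2))
    reject_max1_params: BetaParams = field(default_factory=lambda: BetaParams(2, 5))
    target_diff_params: BetaParams = field(default_factory=lambda: BetaParams(2, 8))
    reject_diff_params: BetaParams = field(default_factory=lambda: BetaParams(8, 2))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target < 1 or self.n_reject < 1:
            raise ConfigurationError("n_target and n_reject must be >= 1")


def sample_tuning_distribution(config: TuningDistributionConfig) -> TuningSample:
    """Draw a TuningSample of n_target target and n_reject reject records.

    Deterministic for a fixed seed; every record satisfies the top-two
    probability geometry by construction.
    """
    rng = np.random.default_rng(config.seed)
    records: list[TuningRecord] = []
    for is_target, n, m1p, gp in (
        (True, config.n_target, config.target_max1_params, config.target_diff_params),
        (False, config.n_reject, config.reject_max1_params, config.reject_diff_params),
    ):
        max1 = m1p.sample(rng, n)
        frac = gp.sample(rng, n)
        max2 = frac * np.minimum(max1, 1.0 - max1)
        for a, b in zip(max1, max2):
            records.append(TuningRecord(max1=float(a), max2=float(b), is_target=is_target))
    return TuningSample(records=records)
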