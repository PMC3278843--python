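"""Training-set-only preprocessing: NZV filter, centering/scaling, PCA.

Mirrors the standard expression-analysis preprocessing chain: near-zero-
variance genes are removed, the remaining genes are centered and scaled to
unit (sample) standard deviation, and the scaled matrix is projected onto
the leading principal components covering a requested fraction of variance.
All statistics are estimated from the training data only and frozen; applying
the fitted model to held-out data never re-estimates anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import ConfigurationError, LabeledExpressionDataset

__all__ = [
    "PreprocessModel",
    "near_zero_variance_filter",
    "fit_preprocessor",
    "apply_preprocessor",
]


@dataclass(frozen=True)
class PreprocessModel:
    """Frozen preprocessing statistics fitted on one training set."""

    gene_ids: tuple[str, ...]          # genes the model was fitted on, in order
    nzv_mask: np.ndarray               # boolean keep-flag per gene
    centers: np.ndarray                # per-kept-gene mean
    scales: np.ndarray                 # per-kept-gene sample sd (> 0)
    pca_rotation: np.ndarray           # (kept genes × n_components) loadings
    n_components: int
    variance_retained: float

    def __post_init__(self) -> None:
        kept = int(self.nzv_mask.sum())
        if self.centers.size != kept or self.scales.size != kept:
            raise ConfigurationError("centers/scales must match number of kept genes")
        if np.any(self.scales <= 0):
            raise ConfigurationError("scales must be > 0 (zero-variance gene leaked)")
        if not (0 < self.variance_retained <= 1):
            raise ConfigurationError("variance_retained must lie in (0, 1]")
        if not (1 <= self.n_components <= kept):
            raise ConfigurationError("n_components must lie in [1, kept genes]")

    # -- persistence -----------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "gene_ids": list(self.gene_ids),
            "nzv_mask": self.nzv_mask.astype(int).tolist(),
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "pca_rotation": self.pca_rotation.tolist(),
            "n_components": self.n_components,
            "variance_retained": self.variance_retained,
        }
        Path(path).write_text(json.dumps(doc))

    @staticmethod
    def from_json(path: str | Path) -> "PreprocessModel":
        doc = json.loads(Path(path).read_text())
        return PreprocessModel(
            gene_ids=tuple(doc["gene_ids"]),
            nzv_mask=np.asarray(doc["nzv_mask"], dtype=bool),
            centers=np.asarray(doc["centers"], dtype=float),
            scales=np.asarray(doc["scales"], dtype=float),
            pca_rotation=np.asarray(doc["pca_rotation"], dtype=float),
            n_components=int(doc["n_components"]),
            variance_retained=float(doc["variance_retained"]),
        )


def near_zero_variance_filter(
    dataset: LabeledExpressionDataset, freq_cut: float = 95 / 5, unique_cut: float = 10.0
) -> np.ndarray:
    """Boolean keep-mask over genes; a gene is *dropped* iff

    * the ratio (frequency of its most common value / frequency of its second
      most common value) exceeds ``freq_cut``, AND
    * its percentage of distinct values, ``100 * n_unique / n_samples``, is
      below ``unique_cut``;
    * or it is constant (always dropped).
    """
    if freq_cut <= 1:
        raise ConfigurationError("freq_cut must be > 1")
    if not (0 < unique_cut < 100):
        raise ConfigurationError("unique_cut must lie in (0, 100)")
    n = dataset.n_samples
    if n < 2:
        raise ConfigurationError("NZV filter undefined on a single-sample dataset")
    keep = np.ones(dataset.n_genes, dtype=bool)
    for j in range(dataset.n_genes):
        col = dataset.values[:, j]
        _, counts = np.unique(col, return_counts=True)
        if counts.size == 1:            # constant gene
            keep[j] = False
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        pct_unique = 100.0 * counts.size / n
        if freq_ratio > freq_cut and pct_unique < unique_cut:
            keep[j] = False
    return keep


def fit_preprocessor(
    train: LabeledExpressionDataset,
    variance_retained: float = 0.95,
    freq_cut: float = 95 / 5,
    unique_cut: float = 10.0,
) -> PreprocessModel:
    """Fit NZV mask, centers/scales and PCA rotation on training data only.

    ``n_components`` is the smallest count of leading components whose
    cumulative explained variance reaches ``variance_retained`` (components
    past the numerical rank of the centered/scaled matrix are never counted).
    """
    if not (0 < variance_retained <= 1):
        raise ConfigurationError("variance_retained must lie in (0, 1]")
    if train.n_samples < 2:
        raise ConfigurationError("need at least 2 training samples")
    mask = near_zero_variance_filter(train, freq_cut, unique_cut)
    if not mask.any():
        raise ConfigurationError("NZV filter removed every gene")
    X = train.values[:, mask]
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    if np.any(scales <= 0):
        # a constant gene always fails the NZV conditions, so this cannot
        # happen unless values are pathological (e.g. NaN already excluded)
        raise ConfigurationError("zero-variance gene survived the NZV filter")
    Z = (X - centers) / scales

    # PCA via SVD of the scaled training matrix
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2  # proportional to per-component variance
    rank = int(np.sum(s > s[0] * 1e-9)) if s.size else 0
    if rank == 0:
        raise ConfigurationError("training matrix has rank 0 after scaling")
    ratios = np.cumsum(var[:rank]) / var[:rank].sum()
    n_comp = int(np.searchsorted(ratios, variance_retained - 1e-12) + 1)
    n_comp = min(n_comp, rank)
    return PreprocessModel(
        gene_ids=tuple(train.gene_ids),
        nzv_mask=mask,
        centers=centers,
        scales=scales,
        pca_rotation=vt[:n_comp].T.copy(),
        n_components=n_comp,
        variance_retained=variance_retained,
    )


def apply_preprocessor(
    model: PreprocessModel, dataset: LabeledExpressionDataset
) -> np.ndarray:
    """Mask, center, scale and rotate ``dataset`` with the frozen model.

    Returns an (n_samples × n_components) score matrix.  Gene ids must match
    the fit exactly (same genes, same order).
    """
    if tuple(dataset.gene_ids) != model.gene_ids:
        missing = sorted(set(model.gene_ids) - set(dataset.gene_ids))
        raise ConfigurationError(
            f"gene ids do not match the fitted model; missing/mismatched: {missing[:5]}"
            if missing
            else "gene ids are reordered relative to the fitted model"
        )
    Z = (dataset.values[:, model.nzv_mask] - model.centers) / model.scales
    return Z @ model.pca_rotation
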