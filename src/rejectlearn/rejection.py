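"""Decision-rule engine for the reject option.

Detecting samples that belong to none of the trained phenotypes is cast as a
binary test on the two highest class-probability estimates of each sample,
``max1`` and ``max2``.  The top-probability axis is split into three zones by
two thresholds ``T_max > T_rej``:

* **reject area** (``max1 < T_rej``): the classifier is so unsure that the
  sample is rejected outright;
* **max area** (``max1 > T_max``): the classifier is confident enough that
  the argmax class is accepted;
* **decision area** (in between): the margin ``max1 − max2`` is consulted,
  with a third threshold ``T_diff``, and a near-tie between two classes whose
  estimates both sit inside the decision area yields an *uncertain* outcome
  (abstention without rejection).

The five rules, applied in order, are::

    R1  : max1 < T_rej            -> REJECT
    R2  : max1 > T_max            -> ACCEPT argmax class
    R3.1: max1 - max2 > T_diff    -> ACCEPT argmax class
    R3.2: max2 > T_rej            -> UNCERTAIN
    R3.3: otherwise               -> REJECT

All comparisons are strict; exact equality at a threshold falls through to
the next rule, so ties are resolved deterministically.

The module also provides the MAX/DIFF kernel-density diagnostic: a Gaussian
KDE of ``max1`` (or of ``max1 − max2``) computed separately for target and
reject samples, from which the thresholds can be read off by eye when the
curves separate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import ConfigurationError

__all__ = [
    "RejectionThresholds",
    "TopTwo",
    "Outcome",
    "Rule",
    "Decision",
    "DensityCurve",
    "top_two",
    "decide",
    "classify_with_rejection",
    "estimate_density",
]


@dataclass(frozen=True)
class RejectionThresholds:
    """The triple (T_max, T_rej, T_diff) driving rules R1–R3.3.

    Requires ``0 <= t_rej < t_max <= 1`` and ``0 <= t_diff <= 1``.
    """

    t_max: float
    t_rej: float
    t_diff: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_rej < self.t_max <= 1.0):
            raise ConfigurationError(
                f"thresholds must satisfy 0 <= t_rej < t_max <= 1, "
                f"got t_rej={self.t_rej}, t_max={self.t_max}"
            )
        if not (0.0 <= self.t_diff <= 1.0):
            raise ConfigurationError(f"t_diff must lie in [0, 1], got {self.t_diff}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.t_max, self.t_rej, self.t_diff], dtype=float)


@dataclass(frozen=True)
class TopTwo:
    """The two highest class-probability estimates of one sample."""

    max1: float
    max2: float
    predicted_class: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.max2 <= self.max1 <= 1.0):
            raise ConfigurationError(
                f"need 0 <= max2 <= max1 <= 1, got max1={self.max1}, max2={self.max2}"
            )
        if self.max1 + self.max2 > 1.0 + 1e-9:
            raise ConfigurationError(
                f"max1 + max2 must not exceed 1, got {self.max1 + self.max2}"
            )


class Outcome(str, enum.Enum):
    ACCEPT = "ACCEPT"
    REJECT = "REJECT"
    UNCERTAIN = "UNCERTAIN"


class Rule(str, enum.Enum):
    R1 = "R1"
    R2 = "R2"
    R3_1 = "R3.1"
    R3_2 = "R3.2"
    R3_3 = "R3.3"


@dataclass(frozen=True)
class Decision:
    """Per-sample outcome plus the rule that produced it."""

    outcome: Outcome
    assigned_class: str | None
    rule_fired: Rule

    def __post_init__(self) -> None:
        accept = self.outcome is Outcome.ACCEPT
        if accept != (self.assigned_class is not None):
            raise ConfigurationError("assigned_class present iff outcome is ACCEPT")
        accept_rules = {Rule.R2, Rule.R3_1}
        reject_rules = {Rule.R1, Rule.R3_3}
        if accept and self.rule_fired not in accept_rules:
            raise ConfigurationError(f"ACCEPT cannot come from {self.rule_fired}")
        if self.outcome is Outcome.REJECT and self.rule_fired not in reject_rules:
            raise ConfigurationError(f"REJECT cannot come from {self.rule_fired}")
        if (self.outcome is Outcome.UNCERTAIN) != (self.rule_fired is Rule.R3_2):
            raise ConfigurationError("UNCERTAIN iff rule R3.2")


def top_two(prob_row: Sequence[float], class_ids: Sequence[str]) -> TopTwo:
    """Extract (max1, max2, argmax class) from one probability row.

    Ties are broken by class-id order: with a stable descending sort, a tied
    maximum goes to the class listed first.
    """
    row = np.asarray(prob_row, dtype=float)
    if row.ndim != 1 or row.size != len(class_ids):
        raise ConfigurationError("probability row length must match class_ids")
    if row.size < 2:
        raise ConfigurationError("need at least 2 classes to form (max1, max2)")
    if np.any(row < -1e-9) or np.any(row > 1 + 1e-9):
        raise ConfigurationError("probabilities must lie in [0, 1]")
    if abs(row.sum() - 1.0) > 1e-6:
        raise ConfigurationError(f"probability row must sum to 1, got {row.sum()}")
    order = np.argsort(-row, kind="stable")
    i1, i2 = int(order[0]), int(order[1])
    return TopTwo(
        max1=float(min(row[i1], 1.0)),
        max2=float(min(row[i2], 1.0)),
        predicted_class=str(class_ids[i1]),
    )


def decide(top: TopTwo, thresholds: RejectionThresholds) -> Decision:
    """Apply rules R1–R3.3 to one sample; exactly one rule fires."""
    t = thresholds
    if top.max1 < t.t_rej:
        return Decision(Outcome.REJECT, None, Rule.R1)
    if top.max1 > t.t_max:
        return Decision(Outcome.ACCEPT, top.predicted_class, Rule.R2)
    if top.max1 - top.max2 > t.t_diff:
        return Decision(Outcome.ACCEPT, top.predicted_class, Rule.R3_1)
    if top.max2 > t.t_rej:
        return Decision(Outcome.UNCERTAIN, None, Rule.R3_2)
    return Decision(Outcome.REJECT, None, Rule.R3_3)


def classify_with_rejection(probs, thresholds: RejectionThresholds) -> list[Decision]:
    """Element-wise ``decide(top_two(row), thresholds)`` over a probability matrix.

    ``probs`` is a :class:`~rejectlearn.classifiers.ProbEstimateMatrix` or any
    object exposing ``probs`` (2-D array) and ``class_ids``.
    """
    rows = np.asarray(probs.probs, dtype=float)
    return [decide(top_two(r, probs.class_ids), thresholds) for r in rows]


# -- MAX/DIFF density diagnostics ---------------------------------------------


@dataclass(frozen=True)
class DensityCurve:
    """A Gaussian kernel density estimate on an even 512-point grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ConfigurationError("bandwidth must be positive")
        if np.any(np.asarray(self.density) < 0):
            raise ConfigurationError("density must be nonnegative")
        integral = float(np.trapezoid(self.density, self.grid))
        if not (0.99 <= integral <= 1.01):
            raise ConfigurationError(f"density integral {integral} outside [0.99, 1.01]")


def _nrd0_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb as used by R's density() default (bw.nrd0):
    0.9 * min(sd, IQR/1.34) * n^(-1/5), with fallbacks for zero spread."""
    n = values.size
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = sd
    if spread <= 0:
        raise ConfigurationError(
            "automatic bandwidth undefined: all values identical (zero spread)"
        )
    return 0.9 * spread * n ** (-1 / 5)


def estimate_density(
    values: Sequence[float], bandwidth: float | str = "auto", grid_size: int = 512
) -> DensityCurve:
    """Gaussian KDE of scores in [0, 1] (max1 values or max1−max2 margins).

    The grid spans ``[min − 3·bw, max + 3·bw]`` with ``grid_size`` even steps;
    the automatic bandwidth is Silverman's rule of thumb.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ConfigurationError("need at least 2 values for a density estimate")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("density input must be finite")
    if bandwidth == "auto":
        bw = _nrd0_bandwidth(x)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ConfigurationError("bandwidth must be positive")
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    # mean of Gaussian kernels centred at the data points
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * math.sqrt(2 * math.pi))
    return DensityCurve(grid=grid, density=dens, bandwidth=bw)
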