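# Methods

## Problem and model

Rejection in a multi-class classifier is modeled as a binary test layered on
top of the classifier's per-sample class-probability estimates.  A *target*
sample truly belongs to one of the trained classes; a *reject* sample belongs
to none.  Only the two highest estimates of each sample are used: `max1`, the
top estimate, and `max2`, the runner-up.  Both obey the probability geometry
`0 ≤ max2 ≤ max1 ≤ 1` and `max1 + max2 ≤ 1`, which the package enforces on
every record.

Two thresholds `T_max > T_rej` split the `max1` axis into a max area
(confident acceptance), a reject area, and a decision area in between, where
a third threshold `T_diff` on the margin `max1 − max2` arbitrates.  The five
rules fire in fixed order (R1, R2, R3.1, R3.2, R3.3; see the README), are
exhaustive and mutually exclusive, and use **strict** comparisons
throughout: exact equality at any threshold falls through to the next rule,
so ties — a measure-zero event for continuous estimates, but common for the
rational-valued vote fractions of k-NN and forests — resolve
deterministically (e.g. `max2 == T_rej` yields REJECT via R3.3).  Argmax ties
inside a probability row go to the class listed first in the class-id order.
UNCERTAIN is a first-class outcome: the rejector abstains without either
assigning a class or claiming the sample is foreign.

## Probability-estimate conventions

The rules are designed for the simple, often uncalibrated estimates that
standard implementations expose:

* **k-NN** — fraction of the k nearest training neighbours per class
  (multiples of 1/k, at most k+1 distinct values);
* **random forest** — fraction of trees voting for the class.  Votes are
  counted explicitly per tree; averaging per-leaf posteriors (the scikit-learn
  default) coincides only when every leaf is pure, so the package counts
  votes itself;
* **single-hidden-layer network** — per-class outputs renormalized to sum
  to 1.

Hyperparameters are selected by leave-group-out cross-validation: repeated
random train/holdout splits (defaults: 5 candidate models, 30 repeats, 98 %
of samples in each split's training part), mean holdout accuracy decides, and
ties go to the simplest candidate so selection is deterministic under a fixed
seed.  Candidate grids: k-NN over odd k starting at 5; random forest with 500
trees and a features-per-split sweep (a single candidate defaults to √p);
network over joint (hidden size, weight decay) pairs.  These grids are
package choices — only the tuning length and resampling scheme are fixed by
convention.

## Preprocessing

Fitted on training data only and frozen: (1) near-zero-variance gene
removal — a gene is dropped iff its most-common/second-most-common value
frequency ratio exceeds `freq_cut` (default 95/5) *and* its percentage of
distinct values is below `unique_cut` (default 10 %); constant genes are
always dropped; (2) centering and unit-variance scaling (sample sd, n−1);
(3) PCA, keeping the smallest number of leading components whose cumulative
explained variance reaches `variance_retained` (default 0.95), never more
than the numerical rank.  Applying the model to held-out data reuses the
frozen statistics; it never re-estimates anything.

## Threshold setup

At training time no genuine reject samples exist, so the tuning sample is
manufactured from the training set: with k trained classes, each class in
turn plays the reject set R, and m folds per held-out class (default m=10;
the bundled experiments use m=3–5 to keep many-repetition runs cheap) each
draw x samples per remaining class as the fold's target test set plus x
samples of R (defaults x=1), without replacement within a fold.  The fold's
classifier and preprocessor are fitted on the remaining samples of the
reduced target set only, so fold test sets never leak into fold training.
Each of the k·m folds contributes `x·(k−1)` target records and `x` reject
records of (max1, max2) statistics.  Folds redraw their test samples
independently rather than partitioning each class across folds; with x small
relative to class size the overlap between folds is modest and the pooled
sample covers the class well.

Requirement k ≥ 3: with two classes the reduced target set would be a single
class and no multi-class fold experiment exists.  A known limitation follows
from the same construction: fold classifiers see k−1 classes while the final
classifier sees k, so the fold `max1` distribution sits on a higher support
(binary classifiers have `max1 ≥ 1/2`) than the deployment distribution.
With small k and weak class separation the tuned `T_rej` can therefore land
above the deployment target mode and the rejector errs on the conservative
side (high specificity, reduced sensitivity).  This is inherent to
leave-one-class-out tuning and fades as k grows.

## Objectives

With uncertain outcomes kept in the denominators —
`Sens = TP/(TP+FN+U_t)`, `Spec = TN/(TN+FP+U_r)` — the registry provides

* `SS  = (1−Sens) + (1−Spec)` — sides contribute independently;
* `SS1 = (1−Sens)² + (1−Spec)²` — the default: quadratic penalty pushes both
  sides up together;
* `SS2 = max(1−Sens, 1−Spec)` — worst side only;
* `FS1`, `FS05` — `1 − F_β` from precision `TP/(TP+FP)` and recall = Sens,
  with β = 1 or 0.5 and value 1 when nothing is accepted.

All are minimized, all are 0 exactly at perfect discrimination, and all are
bounded by 2, which the optimizer's infeasibility penalty (2 + violation)
strictly exceeds.  The registry is pluggable: an objective is any function of
a confusion summary, so alternative uncertain-handling conventions can be
swapped in without touching the optimizer.  Accuracy reporting likewise
offers both conventions (uncertain samples in or out of the denominator;
default in).

## CMA-ES

The optimizer is a standard covariance-matrix-adaptation evolution strategy:
λ candidates per generation sampled from N(m, σ²C) (λ defaults to
4 + ⌊3 ln n⌋ = 7 for the 3-dimensional threshold space), the µ = λ/2 best
recombined with log-rank weights into the next mean, step size adapted via
the conjugate evolution path, and C updated with the standard rank-one plus
rank-µ rule.  Initial mean (0.7, 0.3, 0.2), initial step 0.2.  Box and
ordering constraints (`0 ≤ T_rej < T_max ≤ 1`, `0 ≤ T_diff ≤ 1`) are handled
by penalty, keeping the strategy internally unconstrained and rank-safe.

Stopping, checked in order each generation: (1) best value reaches
`f_lower_bound` (default 0); (2) the objective spread within the current
population falls below δ (default 1e-4 — adequate because count-based
objectives on an n-record sample move in steps of order 1/n); (3) the best
value changes by less than α < δ (default 1e-5) over the last p = 20
generations; (4) 500 generations.  If a run stalls above an objective of
0.2 the search restarts with a doubled population, up to three times — the
standard remedy for premature convergence of small populations.  The whole
procedure is deterministic under a fixed seed, and the reported stop reason's
condition is verifiable from the returned history.

## One-class baselines

Five novelty detectors share one score/threshold interface (higher score =
more anomalous; accept iff score ≤ threshold; threshold = empirical
(1 − rejection_rate) quantile of training scores, default rate 0.1): Parzen
(negative Gaussian-kernel density, Scott bandwidth), k-NN (distance to the
j-th nearest training sample, j=1), k-means (distance to nearest centroid,
≤ 5 clusters), PCA (reconstruction error outside the 90 %-variance
subspace), and an RBF one-class SVM as the enclosing-sphere method.  Two
calibration details matter: Parzen thresholds are computed from
leave-one-out densities (the self-kernel otherwise makes every training
point denser than any test point can be), and the k-NN scorer skips a single
exact zero-distance neighbour so training scores equal leave-one-out
distances and the threshold actually rejects the stated training fraction.
MOCV trains one model per subclass and rejects only if all members reject
(its acceptance region is the union of the members'); SOCMT trains a single
model on the pooled subclasses.

## Synthetic data

`generate_expression_dataset` emulates the structure that makes expression
classification hard: many genes, few samples, and only a small dedicated
subset of genes separating each class.  Background values are i.i.d.
Gaussian log-ratios (sd 1.0); each class's informative block (default 20 of
1000 genes) is mean-shifted by the effect size (default 2.0 log-ratio units)
for that class's samples.  Defaults model a seven-phenotype study with 20
samples per class.  Not emulated: array-specific artifacts (dye bias,
spatial effects, missing spots), gene–gene correlation, and class-specific
covariance — so passing results show the method's behavior under clean
additive signal, not robustness to structured technical noise.
`sample_tuning_distribution` draws (max1, max2) records directly: `max1`
from scaled Beta distributions (targets Beta(8,2), rejects Beta(2,5)) and
`max2` as a Beta-distributed fraction of `min(max1, 1−max1)` — small
fractions for targets (wide margins), near-1 for rejects (near ties) — which
guarantees the probability geometry by construction and reproduces the
qualitative MAX/DIFF density shapes (target margin mode ≈ 0.8, reject ≈ 0).

## Evaluation harness

Confusion accounting treats acceptance of a true target as TP regardless of
the class label assigned — class-level accuracy is the multi-class
classifier's concern, not the rejector's.  Confidence intervals are normal
approximations `mean ± z·sd/√n` (sample sd), clipped to [0, 1] for rates.
ROC curves sweep scrambled-Sobol threshold triples (2000 by default, plus
accept-all/reject-all anchors) for the rules, or the rejection rate for
one-class scorers, and keep the upper-left Pareto staircase; UNCERTAIN
counts as non-acceptance on both axes.  The G_k experiment runner draws
random k-class target panels, balances each test set by downsampling the
larger side, tunes thresholds on training data only, and reports per-method
mean rates with intervals plus the achieved tuning objective per experiment.
The bundled experiment-group runs use a fixed-hyperparameter classifier
configuration inside the tuning folds (single candidate, √p features per
split for the forest) so that many-fold, many-repetition studies stay cheap;
the full leave-group-out selection remains available wherever a single model
is trained.

## Numerical choices and degenerate inputs

Probability rows must sum to 1 within 1e-6 (k-NN and forest rows are exact
rationals up to float rounding).  The Gaussian KDE diagnostic uses a 512-
point grid spanning the data ± 3 bandwidths, Silverman's rule-of-thumb
bandwidth, and refuses zero-spread input under automatic bandwidth.  PCA
rank is cut at singular values below 1e-9 of the largest.  Zero-variance
genes are guaranteed dead by the NZV filter before scaling can divide by
zero.  Threshold triples returned by the optimizer are clipped to the box
and always satisfy `T_rej < T_max` because infeasible candidates carry a
penalty no feasible value can reach and the feasible initial mean is always
evaluated.

## Known limitations

Beyond the fold/deployment class-count mismatch above: objectives are global
(no per-class threshold vectors); no probability calibration is applied (by
design — the point is that raw estimates suffice when paired with the
rules); the confidence intervals assume approximate normality of
per-experiment rates over few repetitions; and the one-class baselines use
rule-of-thumb hyperparameters rather than per-method optimization, so
comparisons against them are qualitative orderings, not tuned-baseline
benchmarks.
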