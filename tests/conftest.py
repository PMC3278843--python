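import numpy as np
import pytest

import rejectlearn as rl


@pytest.fixture(scope="session")
def small_dataset() -> rl.LabeledExpressionDataset:
    """Four well-separated classes, small enough for fast per-fold training."""
    return rl.generate_expression_dataset(
        rl.SynthConfig(
            n_classes=4,
            samples_per_class=10,
            n_genes=120,
            n_informative_per_class=8,
            effect_size=2.5,
            noise_sd=1.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def beta_tuning_sample() -> rl.TuningSample:
    """Default Beta-distribution tuning sample (separable but overlapping)."""
    return rl.sample_tuning_distribution(rl.TuningDistributionConfig(seed=5))


@pytest.fixture(scope="session")
def fast_train_config() -> rl.TrainConfig:
    return rl.TrainConfig(algorithm="knn", n_candidates=1, resampling_repeats=1, seed=3)


def reference_decide(max1: float, max2: float, t_max: float, t_rej: float, t_diff: float) -> str:
    """Independent straight-line transcription of the decision-rule pseudo-code,
    kept free of any package import so it can serve as an oracle."""
    if max1 < t_rej:
        return "REJECT"        # R1
    if max1 > t_max:
        return "ACCEPT"        # R2
    if max1 - max2 > t_diff:
        return "ACCEPT"        # R3.1
    if max2 > t_rej:
        return "UNCERTAIN"     # R3.2
    return "REJECT"            # R3.3


def grid_search_objective(max1, max2, is_target, objective_fn, step=0.01):
    """Exhaustive threshold grid oracle, vectorized independently of the
    package's rule engine.  Returns the best objective value over all valid
    (t_max, t_rej, t_diff) triples on a ``step`` lattice.

    ``objective_fn(tp, fp, tn, fn, unc_t, unc_r)`` maps count arrays to
    objective values (lower better).
    """
    max1 = np.asarray(max1)[None, :]
    max2 = np.asarray(max2)[None, :]
    tgt = np.asarray(is_target, dtype=bool)[None, :]
    axis = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    pairs = [(tm, tr) for tr in axis for tm in axis if tr < tm]
    best = np.inf
    chunk = 4000
    for td in axis:
        for start in range(0, len(pairs), chunk):
            block = pairs[start : start + chunk]
            tm = np.array([p[0] for p in block])[:, None]
            tr = np.array([p[1] for p in block])[:, None]
            r1 = max1 < tr
            r2 = ~r1 & (max1 > tm)
            r31 = ~r1 & ~r2 & ((max1 - max2) > td)
            r32 = ~r1 & ~r2 & ~r31 & (max2 > tr)
            acc = r2 | r31
            rej = ~acc & ~r32
            tp = (acc & tgt).sum(axis=1)
            fp = (acc & ~tgt).sum(axis=1)
            tn = (rej & ~tgt).sum(axis=1)
            fn = (rej & tgt).sum(axis=1)
            ut = (r32 & tgt).sum(axis=1)
            ur = (r32 & ~tgt).sum(axis=1)
            vals = objective_fn(tp, fp, tn, fn, ut, ur)
            m = float(np.min(vals))
            if m < best:
                best = m
    return best
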