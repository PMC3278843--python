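"""Confusion accounting, rates, confidence intervals, ROC, experiment groups."""

import numpy as np
import pytest

import rejectlearn as rl
from rejectlearn.data import ConfigurationError
from rejectlearn.rejection import Decision, Outcome, Rule

ACC = Decision(Outcome.ACCEPT, "x", Rule.R2)
REJ = Decision(Outcome.REJECT, None, Rule.R1)
UNC = Decision(Outcome.UNCERTAIN, None, Rule.R3_2)


class TestTally:
    def test_basic_transcription(self):
        conf = rl.tally_confusion([ACC, REJ, UNC], [True, False, True])
        assert (conf.tp, conf.tn, conf.unc_target) == (1, 1, 1)
        assert conf.fp == conf.fn == conf.unc_reject == 0

    def test_all_uncertain(self):
        conf = rl.tally_confusion([UNC] * 5, [True, True, False, False, False])
        assert conf.tp == conf.tn == conf.fp == conf.fn == 0
        assert (conf.unc_target, conf.unc_reject) == (2, 3)

    def test_totals_partition_input(self):
        rng = np.random.default_rng(0)
        decisions = [rng.choice([ACC, REJ, UNC]) for _ in range(57)]
        truth = rng.uniform(size=57) < 0.5
        conf = rl.tally_confusion(decisions, truth.tolist())
        assert conf.total == 57
        assert conf.n_targets == int(truth.sum())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.tally_confusion([ACC], [True, False])


class TestRates:
    def test_uncertain_aware_arithmetic(self):
        conf = rl.ConfusionSummary(tp=3, fn=1, unc_target=1, tn=4, fp=0, unc_reject=0)
        r = rl.binary_rates(conf)
        assert r.sens == pytest.approx(0.6)
        assert r.spec == pytest.approx(1.0)
        assert r.accuracy == pytest.approx(7 / 9)
        assert r.recall == r.sens

    def test_classical_reduction_without_uncertainty(self):
        conf = rl.ConfusionSummary(tp=8, fn=2, tn=7, fp=3)
        r = rl.binary_rates(conf)
        assert r.sens == pytest.approx(0.8)
        assert r.spec == pytest.approx(0.7)
        assert r.accuracy == pytest.approx(15 / 20)

    def test_all_correct(self):
        r = rl.binary_rates(rl.ConfusionSummary(tp=5, fn=0, tn=5, fp=0))
        assert (r.sens, r.spec, r.precision, r.accuracy) == (1, 1, 1, 1)

    def test_accuracy_denominator_flag(self):
        conf = rl.ConfusionSummary(tp=3, fn=1, unc_target=1, tn=4, fp=0, unc_reject=1)
        assert rl.binary_rates(conf).accuracy == pytest.approx(7 / 10)
        assert rl.binary_rates(conf, include_uncertain_in_accuracy=False).accuracy == pytest.approx(7 / 8)

    def test_empty_side_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.binary_rates(rl.ConfusionSummary(tp=3, fn=1, tn=0, fp=0))


class TestConfidenceInterval:
    def test_constant_values_zero_width(self):
        mean, lo, hi = rl.mean_confidence_interval([0.4] * 6)
        assert mean == pytest.approx(0.4)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_two_point_interval_matches_formula(self):
        # oracle: mean ± z_{0.975} · sd(n−1) / sqrt(n) for {0, 1}
        from scipy.stats import norm

        sd = np.std([0, 1], ddof=1)
        half = norm.ppf(0.975) * sd / np.sqrt(2)
        mean, lo, hi = rl.mean_confidence_interval([0, 1], 0.95)
        assert mean == pytest.approx(0.5)
        assert hi - mean == pytest.approx(half)
        # clipped variant for rates
        _, lo_c, hi_c = rl.mean_confidence_interval([0, 1], 0.95, clip=(0, 1))
        assert lo_c == 0.0 and hi_c == 1.0

    def test_interval_contains_mean_and_needs_two_values(self):
        mean, lo, hi = rl.mean_confidence_interval([0.2, 0.5, 0.8])
        assert lo <= mean <= hi
        with pytest.raises(ConfigurationError):
            rl.mean_confidence_interval([1.0])


class TestROC:
    def test_rule_sweep_has_endpoints_and_monotone_staircase(self, beta_tuning_sample):
        m1, m2, t = beta_tuning_sample.arrays()
        roc = rl.roc_points_rules(m1, m2, t, n_triples=128, seed=0)
        stair = roc.staircase()
        assert (0.0, 0.0) in [(round(f, 9), round(tp, 9)) for f, tp, *_ in [(p[0], p[1]) for p in stair]] or stair[0] == (0.0, 0.0)
        fprs = [p[0] for p in stair]
        tprs = [p[1] for p in stair]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)
        assert max(tprs) == 1.0 and min(tprs) == 0.0

    def test_perfectly_separated_sample_reaches_corner(self):
        # targets above 0.7 with big margins, rejects below 0.45: the explicit
        # separating triple reaches (FPR 0, TPR 1), so the sweep's staircase
        # must contain (0, 1) once that triple is included
        rng = np.random.default_rng(1)
        m1 = np.concatenate([rng.uniform(0.75, 0.95, 50), rng.uniform(0.2, 0.4, 50)])
        m2 = np.concatenate([rng.uniform(0, 0.05, 50), rng.uniform(0.15, 0.2, 50)])
        t = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        sep = rl.RejectionThresholds(t_max=0.6, t_rej=0.5, t_diff=0.99)
        roc = rl.roc_points_rules(m1, m2, t, n_triples=64, seed=2, extra_triples=[sep])
        assert (0.0, 1.0) in roc.staircase()

    def test_one_class_sweep_bounds(self):
        rng = np.random.default_rng(3)
        train_scores = rng.uniform(0, 1, 100)
        test_scores = np.concatenate([rng.uniform(0, 0.5, 30), rng.uniform(0.8, 2, 30)])
        truth = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        roc = rl.roc_points_one_class(train_scores, test_scores, truth)
        stair = roc.staircase()
        assert stair[0][1] >= 0.0 and stair[-1][1] == 1.0


@pytest.fixture(scope="module")
def group_result():
    ds = rl.generate_expression_dataset(
        rl.SynthConfig(n_classes=5, samples_per_class=8, n_genes=80,
                       n_informative_per_class=6, effect_size=2.5, seed=31)
    )
    cfg = rl.TrainConfig(algorithm="knn", n_candidates=1, resampling_repeats=1, seed=0)
    return rl.run_experiment_group(
        ds, k_target=3, n_experiments=3, algorithms=["knn"],
        baselines=["kmeans_oc"], baseline_modes=["socmt"],
        m_folds=2, train_config=cfg, seed=17,
    )


class TestExperimentGroup:
    def test_summary_shape(self, group_result):
        summary = group_result.summary
        assert set(summary["method"]) == {"knn+rule", "kmeans_oc-socmt"}
        for col in ("sens", "sens_lo", "sens_hi", "spec", "accuracy_hi"):
            assert col in summary.columns
        assert len(group_result.achieved_objectives) == 3

    def test_balanced_test_sets(self, group_result):
        per = group_result.per_experiment
        # sens and spec denominators are equal by construction, so
        # accuracy = (sens + spec) / 2 exactly when uncertain included
        rules = per[per.method == "knn+rule"]
        np.testing.assert_allclose(
            rules.accuracy, (rules.sens + rules.spec) / 2, atol=1e-12
        )

    def test_objective_recorded_per_experiment(self, group_result):
        assert all(0 <= v <= 2 for v in group_result.achieved_objectives)

    def test_too_few_classes_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            rl.run_experiment_group(small_dataset, k_target=4, n_experiments=1)
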