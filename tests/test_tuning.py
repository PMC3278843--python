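"""Fold generation, tuning objectives and CMA-ES threshold optimization."""

import numpy as np
import pytest

import rejectlearn as rl
from rejectlearn.data import ConfigurationError
from rejectlearn.tuning import confusion_from_records

from .conftest import grid_search_objective


def _planted_sample(n=200, boundary=0.6, seed=0):
    """Records with a planted separation: targets above boundary+0.1 with
    large margins, rejects below boundary-0.1 with near-tied estimates."""
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        m1 = rng.uniform(boundary + 0.1, 0.98)
        records.append(rl.TuningRecord(m1, float(rng.uniform(0, 0.2) * min(m1, 1 - m1)),
                                       True))
    for _ in range(n):
        m1 = rng.uniform(0.2, boundary - 0.1)
        records.append(rl.TuningRecord(m1, float(rng.uniform(0.8, 1.0) * min(m1, 1 - m1)),
                                       False))
    return rl.TuningSample(records=records)


class TestFoldGeneration:
    def test_counts_and_sizes(self, small_dataset):
        target, _ = rl.split_target_reject(small_dataset, {"A", "B", "C"})
        folds = rl.generate_rejection_folds(target, m=2, x=1, seed=0)
        assert len(folds) == 3 * 2
        for f in folds:
            assert len(f.test_target_ids) == 1 * (3 - 1)
            assert len(f.test_reject_ids) == 1
            assert all(
                target.labels[target.sample_ids.index(s)] == f.held_out_class
                for s in f.test_reject_ids
            )

    def test_train_test_disjoint_and_reject_class_absent_from_train(self, small_dataset):
        folds = rl.generate_rejection_folds(small_dataset, m=3, x=2, seed=1)
        lab = dict(zip(small_dataset.sample_ids, small_dataset.labels))
        for f in folds:
            train = set(f.train_sample_ids)
            test = set(f.test_target_ids) | set(f.test_reject_ids)
            assert not train & test
            assert all(lab[s] != f.held_out_class for s in f.train_sample_ids)
            assert all(lab[s] != f.held_out_class for s in f.test_target_ids)

    def test_seed_determinism(self, small_dataset):
        a = rl.generate_rejection_folds(small_dataset, m=2, x=1, seed=9)
        b = rl.generate_rejection_folds(small_dataset, m=2, x=1, seed=9)
        assert a == b

    def test_two_classes_rejected(self, small_dataset):
        target, _ = rl.split_target_reject(small_dataset, {"A", "B"})
        with pytest.raises(ConfigurationError):
            rl.generate_rejection_folds(target, m=2, x=1)

    def test_class_not_larger_than_x_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError, match="'A'"):
            rl.generate_rejection_folds(small_dataset, m=1, x=10)


class TestCollectTuningSample:
    def test_record_counts_and_geometry(self, small_dataset, fast_train_config):
        target, _ = rl.split_target_reject(small_dataset, {"A", "B", "C"})
        folds = rl.generate_rejection_folds(target, m=2, x=1, seed=0)
        sample = rl.collect_tuning_sample(target, folds, fast_train_config)
        m1, m2, t = sample.arrays()
        assert len(sample.records) == 6 * 3      # k·m folds × (x·(k−1)+x) samples
        assert int(t.sum()) == 12 and int((~t).sum()) == 6
        assert np.all((0 <= m2) & (m2 <= m1) & (m1 <= 1))
        assert np.all(m1 + m2 <= 1 + 1e-9)

    def test_separable_classes_give_ordered_max1_means(self, small_dataset, fast_train_config):
        target, _ = rl.split_target_reject(small_dataset, {"A", "B", "C"})
        folds = rl.generate_rejection_folds(target, m=3, x=1, seed=2)
        sample = rl.collect_tuning_sample(target, folds, fast_train_config)
        m1, _, t = sample.arrays()
        assert m1[t].mean() > m1[~t].mean()


class TestObjectives:
    def test_perfect_discrimination_scores_zero_everywhere(self):
        conf = rl.ConfusionSummary(tp=50, tn=50, fp=0, fn=0)
        for name in ("SS", "SS1", "SS2", "FS1", "FS05"):
            assert rl.objective_value(rl.ObjectiveSpec(name), conf) == pytest.approx(0.0)

    def test_ss1_arithmetic(self):
        # Sens=0.61, Spec=0.76 -> SS1 = 0.39^2 + 0.24^2 = 0.2097
        conf = rl.ConfusionSummary(tp=61, fn=39, tn=76, fp=24)
        assert rl.objective_value(rl.ObjectiveSpec("SS1"), conf) == pytest.approx(0.2097)
        assert rl.objective_value(rl.ObjectiveSpec("SS"), conf) == pytest.approx(0.63)
        assert rl.objective_value(rl.ObjectiveSpec("SS2"), conf) == pytest.approx(0.39)

    def test_one_sided_failure(self):
        conf = rl.ConfusionSummary(tp=10, fn=0, tn=0, fp=10)
        for name in ("SS", "SS1", "SS2"):
            assert rl.objective_value(rl.ObjectiveSpec(name), conf) == pytest.approx(1.0)

    def test_fscore_degenerate_convention(self):
        # nothing accepted: precision = recall = 0 -> objective 1
        conf = rl.ConfusionSummary(tp=0, fn=10, tn=10, fp=0)
        assert rl.objective_value(rl.ObjectiveSpec("FS1"), conf) == 1.0
        assert rl.objective_value(rl.ObjectiveSpec("FS05"), conf) == 1.0

    def test_uncertain_counts_stay_in_denominators(self):
        conf = rl.ConfusionSummary(tp=6, fn=1, unc_target=3, tn=8, fp=0, unc_reject=2)
        # Sens = 6/10, Spec = 8/10
        assert rl.objective_value(rl.ObjectiveSpec("SS"), conf) == pytest.approx(0.6)

    def test_empty_side_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.objective_value(rl.ObjectiveSpec("SS"), rl.ConfusionSummary(tp=5, fn=5, tn=0, fp=0))

    def test_beta_fixed_by_variant(self):
        assert rl.ObjectiveSpec("FS1").beta == 1.0
        assert rl.ObjectiveSpec("FS05").beta == 0.5
        with pytest.raises(ConfigurationError):
            rl.ObjectiveSpec("F2")


class TestOptimizeThresholds:
    def test_planted_separation_recovered_on_fresh_sample(self):
        sample = _planted_sample(seed=1)
        thresholds, achieved = rl.optimize_thresholds(
            sample, rl.ObjectiveSpec("SS1"), rl.CMAESConfig(seed=4)
        )
        assert achieved == pytest.approx(0.0, abs=1e-12)
        fresh = _planted_sample(seed=2)
        m1, m2, t = fresh.arrays()
        conf = confusion_from_records(m1, m2, t, thresholds.as_vector())
        rates = rl.binary_rates(conf)
        assert rates.sens == 1.0 and rates.spec == 1.0

    def test_identical_distributions_cannot_be_separated(self):
        cfg = rl.TuningDistributionConfig(
            n_target=300, n_reject=300,
            reject_max1_params=rl.BetaParams(8, 2),
            reject_diff_params=rl.BetaParams(2, 8),
            seed=6,
        )
        sample = rl.sample_tuning_distribution(cfg)
        _, achieved = rl.optimize_thresholds(
            sample, rl.ObjectiveSpec("SS1"), rl.CMAESConfig(seed=3)
        )
        assert achieved >= 0.45

    def test_thresholds_always_feasible(self, beta_tuning_sample):
        for seed in (0, 1, 2):
            th, _ = rl.optimize_thresholds(
                beta_tuning_sample, rl.ObjectiveSpec("SS1"), rl.CMAESConfig(seed=seed)
            )
            assert 0 <= th.t_rej < th.t_max <= 1
            assert 0 <= th.t_diff <= 1

    def test_achieved_value_is_recomputable(self, beta_tuning_sample):
        th, achieved = rl.optimize_thresholds(
            beta_tuning_sample, rl.ObjectiveSpec("SS2"), rl.CMAESConfig(seed=8)
        )
        m1, m2, t = beta_tuning_sample.arrays()
        again = rl.objective_value(
            rl.ObjectiveSpec("SS2"), confusion_from_records(m1, m2, t, th.as_vector())
        )
        assert achieved == pytest.approx(again, abs=1e-12)

    def test_close_to_grid_oracle_on_one_objective(self, beta_tuning_sample):
        # full five-objective sweep runs in the acceptance suite; one here
        m1, m2, t = beta_tuning_sample.arrays()

        def ss1(tp, fp, tn, fn, ut, ur):
            sens = tp / (tp + fn + ut)
            spec = tn / (tn + fp + ur)
            return (1 - sens) ** 2 + (1 - spec) ** 2

        grid_best = grid_search_objective(m1, m2, t, ss1, step=0.02)
        _, achieved = rl.optimize_thresholds(
            beta_tuning_sample, rl.ObjectiveSpec("SS1"), rl.CMAESConfig(seed=5)
        )
        assert achieved <= grid_best + 0.02
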