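"""Decision rules, top-two extraction and the KDE diagnostic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rejectlearn as rl
from rejectlearn.data import ConfigurationError
from rejectlearn.rejection import Outcome, Rule

from .conftest import reference_decide

THR = rl.RejectionThresholds(t_max=0.8, t_rej=0.3, t_diff=0.2)


class TestTopTwo:
    def test_plain_ordering(self):
        t = rl.top_two([0.7, 0.2, 0.1], ["c1", "c2", "c3"])
        assert (t.max1, t.max2, t.predicted_class) == (0.7, 0.2, "c1")

    def test_tie_goes_to_first_class(self):
        t = rl.top_two([0.0, 0.5, 0.5], ["a", "b", "c"])
        assert t.max1 == t.max2 == 0.5
        assert t.predicted_class == "b"

    def test_uniform_row(self):
        t = rl.top_two([0.25] * 4, list("abcd"))
        assert t.max1 == t.max2 == 0.25

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.top_two([1.0], ["a"])

    def test_non_normalized_row_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.top_two([0.9, 0.3], ["a", "b"])


class TestDecide:
    @pytest.mark.parametrize(
        "max1,max2,outcome,rule",
        [
            (0.20, 0.10, Outcome.REJECT, Rule.R1),
            (0.95, 0.05, Outcome.ACCEPT, Rule.R2),
            (0.60, 0.30, Outcome.ACCEPT, Rule.R3_1),
            (0.50, 0.45, Outcome.UNCERTAIN, Rule.R3_2),
            (0.50, 0.25, Outcome.ACCEPT, Rule.R3_1),
        ],
    )
    def test_rule_table(self, max1, max2, outcome, rule):
        d = rl.decide(rl.TopTwo(max1, max2, "c2"), THR)
        assert (d.outcome, d.rule_fired) == (outcome, rule)
        if outcome is Outcome.ACCEPT:
            assert d.assigned_class == "c2"
        else:
            assert d.assigned_class is None

    def test_border_noise_rejected_by_r33(self):
        # same (max1, max2) as the last accept case but with a larger t_diff:
        # the margin no longer suffices and max2 sits below t_rej
        d = rl.decide(
            rl.TopTwo(0.50, 0.25, "c1"),
            rl.RejectionThresholds(t_max=0.8, t_rej=0.3, t_diff=0.3),
        )
        assert (d.outcome, d.rule_fired) == (Outcome.REJECT, Rule.R3_3)

    def test_threshold_equality_falls_through(self):
        # max1 == t_rej is NOT in the reject area (strict comparison)
        d = rl.decide(rl.TopTwo(0.3, 0.0, "a"), THR)
        assert d.rule_fired is Rule.R3_1
        # max2 == t_rej falls through R3.2 to R3.3
        d = rl.decide(rl.TopTwo(0.45, 0.3, "a"), THR)
        assert (d.outcome, d.rule_fired) == (Outcome.REJECT, Rule.R3_3)
        # max1 == t_max is NOT in the max area (falls into the decision area)
        d = rl.decide(
            rl.TopTwo(0.5, 0.45, "a"),
            rl.RejectionThresholds(t_max=0.5, t_rej=0.3, t_diff=0.2),
        )
        assert d.rule_fired is Rule.R3_2

    def test_matches_reference_transcription_on_grid(self):
        # small lattice here; the full ~100k-case sweep runs in the acceptance suite
        rng = np.random.default_rng(0)
        for _ in range(5):
            tr, tm = np.sort(rng.uniform(0, 1, 2))
            if tm <= tr:
                tm = tr + 1e-6
            thr = rl.RejectionThresholds(t_max=min(tm, 1.0), t_rej=tr,
                                         t_diff=float(rng.uniform(0, 1)))
            for m1 in np.arange(0.0, 1.0001, 0.05):
                for m2 in np.arange(0.0, min(m1, 1 - m1) + 1e-9, 0.05):
                    got = rl.decide(rl.TopTwo(float(m1), float(m2), "x"), thr)
                    want = reference_decide(m1, m2, thr.t_max, thr.t_rej, thr.t_diff)
                    assert got.outcome.value == want

    @given(
        m1=st.floats(0, 1), frac=st.floats(0, 1),
        tr=st.floats(0, 0.99), gap=st.floats(1e-6, 1), td=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_exactly_one_rule_fires(self, m1, frac, tr, gap, td):
        m2 = frac * min(m1, 1 - m1)
        thr = rl.RejectionThresholds(t_max=min(tr + gap, 1.0), t_rej=tr, t_diff=td)
        d = rl.decide(rl.TopTwo(m1, m2, "x"), thr)
        # Decision's own invariants guarantee outcome/rule consistency;
        # reaching here means exactly one branch produced exactly one decision
        assert d.rule_fired in set(Rule)

    def test_raising_t_rej_never_converts_reject_to_accept(self):
        for m1 in np.arange(0.0, 1.001, 0.01):
            previous = None
            for tr in (0.1, 0.3, 0.5, 0.7):
                thr = rl.RejectionThresholds(t_max=tr + 1e-9 + 0.2, t_rej=tr, t_diff=0.0)
                out = rl.decide(rl.TopTwo(float(m1), 0.0, "x"), thr).outcome
                if previous is Outcome.REJECT:
                    assert out is Outcome.REJECT
                previous = out

    def test_degenerate_thresholds_reduce_to_argmax(self):
        eps = 1e-6
        thr = rl.RejectionThresholds(t_max=eps, t_rej=0.0, t_diff=0.0)
        for m1 in (0.3, 0.5, 0.9):
            d = rl.decide(rl.TopTwo(m1, min(m1, 1 - m1) / 2, "top"), thr)
            assert d.outcome is Outcome.ACCEPT and d.assigned_class == "top"


class TestClassifyWithRejection:
    def test_order_and_length_preserved(self):
        probs = rl.ProbEstimateMatrix(
            class_ids=["a", "b", "c"],
            probs=np.array([[0.9, 0.05, 0.05], [0.4, 0.35, 0.25], [0.2, 0.2, 0.6]]),
            sample_ids=["s1", "s2", "s3"],
        )
        decisions = rl.classify_with_rejection(probs, THR)
        assert len(decisions) == 3
        assert decisions[0].assigned_class == "a"

    def test_uniform_rows_rejected_when_t_rej_above_chance(self):
        k = 4
        probs = rl.ProbEstimateMatrix(
            class_ids=list("abcd"), probs=np.full((5, k), 1 / k),
            sample_ids=[f"s{i}" for i in range(5)],
        )
        thr = rl.RejectionThresholds(t_max=0.8, t_rej=0.3, t_diff=0.2)  # 0.3 > 1/4
        decisions = rl.classify_with_rejection(probs, thr)
        assert all(d.rule_fired is Rule.R1 for d in decisions)

    def test_invalid_threshold_construction_fails_first(self):
        with pytest.raises(ConfigurationError):
            rl.RejectionThresholds(t_max=0.0, t_rej=0.3, t_diff=0.2)


class TestDensity:
    def test_peak_at_single_location(self):
        vals = [0.5] * 10 + [0.49, 0.51]
        curve = rl.estimate_density(vals, bandwidth=0.05)
        assert curve.grid[int(np.argmax(curve.density))] == pytest.approx(0.5, abs=0.01)

    def test_integral_close_to_one(self):
        rng = np.random.default_rng(1)
        curve = rl.estimate_density(rng.uniform(0, 1, 200), "auto")
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=0.01)

    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, 100)
        bw = 0.07
        curve = rl.estimate_density(vals, bw)
        brute = np.array(
            [
                sum(math.exp(-0.5 * ((g - v) / bw) ** 2) for v in vals)
                / (len(vals) * bw * math.sqrt(2 * math.pi))
                for g in curve.grid
            ]
        )
        np.testing.assert_allclose(curve.density, brute, atol=1e-10)

    def test_zero_spread_auto_bandwidth_rejected(self):
        with pytest.raises(ConfigurationError):
            rl.estimate_density([0.4] * 20, "auto")
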