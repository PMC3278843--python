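"""Apply the three-threshold decision rules to class-probability estimates.

Builds a small probability matrix by hand, applies thresholds
(T_max=0.8, T_rej=0.3, T_diff=0.2) and prints the outcome and the rule that
fired for each sample.  High-confidence rows are accepted (R2), confident
margins inside the decision area are accepted (R3.1), near-ties between two
plausible classes abstain as uncertain (R3.2), and low-confidence rows are
rejected (R1/R3.3).
"""

import numpy as np

import rejectlearn as rl

probs = rl.ProbEstimateMatrix(
    class_ids=["ALL", "CLL", "DLBCL"],
    probs=np.array(
        [
            [0.90, 0.06, 0.04],   # confident: max area
            [0.60, 0.30, 0.10],   # decision area, wide margin
            [0.50, 0.45, 0.05],   # decision area, near tie between two classes
            [0.20, 0.15, 0.65],   # confident in the third class
            [0.34, 0.33, 0.33],   # near-uniform: two classes inside the decision area
            [0.25, 0.05, 0.70],   # decision area again
        ]
    ),
    sample_ids=[f"sample{i}" for i in range(1, 7)],
)

thresholds = rl.RejectionThresholds(t_max=0.8, t_rej=0.3, t_diff=0.2)
decisions = rl.classify_with_rejection(probs, thresholds)

print(f"thresholds: T_max={thresholds.t_max} T_rej={thresholds.t_rej} T_diff={thresholds.t_diff}")
for sid, d, row in zip(probs.sample_ids, decisions, probs.probs):
    tt = rl.top_two(row, probs.class_ids)
    assigned = d.assigned_class or "-"
    print(f"{sid}: max1={tt.max1:.2f} max2={tt.max2:.2f} -> "
          f"{d.outcome.value:<9} class={assigned:<6} rule={d.rule_fired.value}")

# The printed rules show each sample routed through exactly one branch of the
# decision process; an UNCERTAIN outcome means the classifier saw two nearly
# tied plausible classes and abstained rather than guessing.
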