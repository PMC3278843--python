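"""Compare rule-based rejection against one-class baselines (G_k design).

Runs a small experiment group on synthetic 5-class data: each experiment
draws a random 3-class target panel, tunes the rejection thresholds on
training data only, and evaluates the random-forest + rules pipeline and the
SOCMT one-class baselines on a balanced test set of target and unknown-class
samples.
"""

import rejectlearn as rl
from rejectlearn.oneclass import ONE_CLASS_METHODS

ds = rl.generate_expression_dataset(
    rl.SynthConfig(n_classes=5, samples_per_class=14, n_genes=400,
                   n_informative_per_class=15, effect_size=2.0, seed=42)
)
result = rl.run_experiment_group(
    ds, k_target=3, n_experiments=4,
    algorithms=["rf"], baselines=list(ONE_CLASS_METHODS),
    baseline_modes=["socmt"], m_folds=4, seed=9,
)

print(result.summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nachieved SS1 objective per experiment:",
      [round(v, 3) for v in result.achieved_objectives])

# Accuracy on balanced test sets equals (sens + spec) / 2; the rule-based
# forest typically leads the one-class baselines, which suffer from distance
# concentration in the high-dimensional expression space.  The SS1 objective
# column is the reliability indicator: lower values mean the tuning folds
# separated targets from rejects more cleanly.
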