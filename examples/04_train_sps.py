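"""Train a synthetic problem solver on generated problems and deploy it.

Collects per-iteration features + detection flags over a small training
grid, learns the warm-up classification tree, reports its cross-validated
accuracy, and writes the deployable JSON descriptor.
"""

from spskit import ProblemGrid, TrainingConfig, generate_problem_set, save_descriptor, train_sps

grid = ProblemGrid(bias_fractions=(0.1, 0.4), noise_levels=(0.0, 25.0),
                   lengths=(1000,), replications=3)
problems = generate_problem_set(grid, seed=21)
definition, descriptor, cv = train_sps(problems, config=TrainingConfig(seed=21))
print(f"trained on {len(problems)} series; "
      f"cross-validated accuracy {sum(cv)/len(cv):.3f}")
save_descriptor(definition, "sps.json")
print("descriptor written to sps.json "
      f"({len(definition.solvers)} baseline solvers, tree over features + flags)")
# Accuracy well above the majority-class rate means the tree actually uses
# the features/flags to decide whether the warm-up phase is over.
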