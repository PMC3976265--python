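"""Compare the trained SPS against the ten baseline estimators.

Each problem is chunked 5+5 around its ideal truncation point (the
replicated-MSE rule); every solver is scored for accuracy (relative error),
robustness (did the first estimate come after the truncation point?) and
data efficiency (how many chunks past it).
"""

from spskit import ProblemGrid
from spskit.study import run_study

result = run_study(seed=7, repetitions=2,
                   training_grid=ProblemGrid(bias_fractions=(0.1, 0.4),
                                             noise_levels=(0.0, 25.0),
                                             lengths=(1000,), replications=3),
                   test_grid=ProblemGrid(bias_fractions=(0.25,),
                                         noise_levels=(10.0,),
                                         lengths=(1000,), replications=2))
s = result.summary
print(f"SPS median relative error:            {s['sps_median_rel_error']:.4f}")
print(f"best baseline ({s['best_baseline']}): {s['best_baseline_median_rel_error']:.4f}")
print(f"SPS positive-index fraction:          {s['sps_positive_index_fraction']:.2f}")
# A smaller median error than every individual estimator, with a high
# positive-index fraction, is the composition benefit: the tree delays the
# estimate until the warm-up is over, then averages the available results.
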