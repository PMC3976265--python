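"""Drive an estimator iteratively, the way a simulator would feed it.

The solver sees the trajectory chunk by chunk and requests more data until
its detector accepts; the management loop stops at the first defined
estimate or when the data source is exhausted.
"""

import numpy as np

from spskit import ChunkedSource, EstimatorSolver, GeneratorSpec, generate_series, run_solver

labeled = generate_series(
    GeneratorSpec(n=1000, bias_fraction=0.2, trend="quadratic", shape="oscillating",
                  noise_low=5, noise_high=5, autocorr=0.3, seed=11)
)
chunks = np.array_split(labeled.values, 10)
estimate = run_solver(
    EstimatorSolver("batch_mean"),
    p0=chunks[0],
    source=ChunkedSource(chunks[1:]),
    max_iterations=10,
)
print(f"true steady mean: {labeled.true_mean}")
print(f"iterative batch-means estimate: {estimate}")
# The estimate is produced as soon as the detector accepts a prefix; None
# would mean the full series was consumed without a detection.
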