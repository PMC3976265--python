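"""Detect the warm-up phase of a simulated trajectory with one estimator.

Builds a trajectory that starts at a biased level and settles to a steady
mean of 10, then runs the MSER detector and reports the truncation point
and the resulting steady-state mean estimate.
"""

from spskit import DETECTORS, GeneratorSpec, estimate_mean, generate_series

labeled = generate_series(
    GeneratorSpec(n=1000, bias_fraction=0.3, trend="quadratic", shape="line",
                  steady_mean=10.0, bias_amplitude=5.0,
                  noise_low=10, noise_high=10, autocorr=0.3, seed=4)
)
print(f"true steady mean {labeled.true_mean}, true warm-up length {labeled.warmup_length}")

for estimator_id in ("mser", "batch_mean", "schruben"):
    det = DETECTORS[estimator_id](labeled.values)
    if det.found:
        est = estimate_mean(labeled.values, det.truncation)
        err = abs(est - labeled.true_mean) / labeled.true_mean
        print(f"{estimator_id:11s} truncates {det.truncation:4d} points -> "
              f"estimate {est:.3f} (relative error {err:.2%})")
    else:
        print(f"{estimator_id:11s} found no steady state")
# A truncation near the true warm-up length and a small relative error mean
# the detector removed the initialization bias without discarding good data.
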