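"""Extract the 13-dimensional feature vector that the SPS conditions on.

Counts of values above/below the mean (length-normalized), extreme
deviations (range-normalized) and a portmanteau autocorrelation statistic,
each computed on the raw series and on its exponentially smoothed trend.
"""

from spskit import GeneratorSpec, extract_problem_features, generate_series

biased = generate_series(GeneratorSpec(n=500, bias_fraction=0.4, shape="line",
                                       noise_low=10, noise_high=10, seed=2))
steady = generate_series(GeneratorSpec(n=500, bias_fraction=0.0, bias_amplitude=0.0,
                                       noise_low=10, noise_high=10, seed=2))
for name, labeled in (("biased", biased), ("steady", steady)):
    fv = extract_problem_features(labeled.values)
    print(f"{name}: frac_above={fv.frac_above:.3f} frac_below={fv.frac_below:.3f} "
          f"t_max_pos={fv.t_max_pos_dist:.3f} t_max_neg={fv.t_max_neg_dist:.3f}")
# The biased series is asymmetric around its mean (few points above, many
# below), which is exactly the signature the warm-up classifier keys on.
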