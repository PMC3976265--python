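# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `spskit`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## The iterative solver contract

A problem solver consumes an *iterated problem* — an initial time series
plus an append-only history of (request, answer-segment) pairs — and
returns a state holding its scratch payload, a boolean request for more
data, and a result that is either a steady-state mean estimate or
undefined. The management loop (`core.run_solver`) alternates solve calls
with answer segments until the solver stops requesting, the source is
exhausted, or an iteration budget is reached; exhaustion yields the
undefined result rather than an exception, because "no estimate produced"
is a first-class outcome in the evaluation harness. The loop guarantees at
most `max_iterations` solve calls and exactly one history entry per granted
request. Answers are restricted to contiguous segments of one trajectory;
the interface would admit other answer types, but every solver in this
package consumes time series.

## Baseline detectors

All ten detectors share three conventions. (1) *Minimum data*: below 10
observations nothing is detected — no method in this collection can make a
defensible call on less, and a uniform floor keeps the solvers' iterative
behavior comparable. (2) *Zero variance*: a constant series of sufficient
length is a steady state, detected at truncation 0, regardless of
detector-specific batching requirements. (3) *Ties* break toward the
smallest qualifying truncation. Insufficient data never raises; it returns
"not found". After detection, every estimator returns the arithmetic mean
of the retained suffix, so accuracy differences between estimators reflect
truncation quality only.

Default parameters (all overridable through `EstimatorParams`): MSER
minimum retained 10; Euclidean window 10, run 3, ε 0.1; goodness-of-fit
batch 25, α 0.05; balancing δ 0.02; running mean window 25, ε 0.01; batch
means size 25, groups 5, α 0.05; crossing count 25; stop-crossing length
50; Schruben α 0.05, 10 batches, scan step ⌈n/10⌉; moving window 100, run
5, θ 0.05. These are values typical of the output-analysis literature,
frozen for reproducibility; no parameter-sensitivity study is attempted.

Choices that were genuinely open:

* **Euclidean distance normalization.** The method's published description
  leaves the vector normalization unspecified. Scaling each vector by its
  own norm makes every constant vector equal to the unit direction, so a
  warm-up at a shifted constant level would be indistinguishable from the
  steady level. Each vector is therefore scaled by the norm of the *last*
  vector — the trailing level being the best available proxy for the
  steady level — and compared to the all-ones direction. On a step series
  this detects the first all-steady vector boundary; on constants it
  detects at 0.
* **Schruben's test.** The partial sums S_k = k(ȳ − ȳ_k) of a stationary
  suffix approximate a Brownian bridge; the test statistic is their sum
  standardized by √(σ̂²·m(m²−1)/12) and referred to a t distribution with
  (batches − 1) degrees of freedom. The variance parameter σ̂² is a
  batch-means estimate computed from the *second half* of the suffix,
  which initialization bias is assumed not to reach: estimating it from
  the full suffix lets the bias inflate the variance and mask itself
  (measured: a 50-point level shift in a 200-point series went undetected
  with the full-suffix estimate). The empirical acceptance rate at
  truncation 0 on white noise is ≈ 1 − α (0.945 over 200 replications,
  asserted in the test suite).
* **Batch means.** "Split the remainder into 2g batches" is read as 2g
  equal batches spanning the whole remainder (the batch-size parameter is
  the scan step); if both groups of batch means have zero variance the
  candidate is accepted only when the groups sit at the same level.
* **Crossing-based methods** treat a zero deviation from the running mean
  as inheriting the previous sign, so flat stretches do not generate
  spurious crossings.

## Problem features

Thirteen features: fraction of values above/below the sample mean and
their difference (divided by n), maximum positive/negative deviation from
the mean (divided by the value range), and a Box–Pierce portmanteau
statistic Q = n·Σ r_k² over 10 lags (also divided by the range), computed
on the raw series; the same seven, plus the maximum absolute deviation, on
an exponentially smoothed trend curve (s_i = α·x_i + (1−α)·s_{i−1},
α = 0.1, s_1 = x_1). The raw maximum-absolute-deviation feature is
excluded: it is redundant given the signed extremes and invites the
classifier to overfit. Values exactly equal to the mean count to neither
side. A zero-range series yields zeros for all range-normalized features;
when the series is too short for 10 lags the lag count is reduced to
n − 1. Note that dividing the (already unitless) portmanteau statistic by
the range follows the uniform normalization rule at the cost of scale
invariance; the count and distance features are invariant under positive
affine transforms, and the tests assert exactly that set.

The single state feature is the detection flag: whether a solver's pending
request is false, i.e. it considers the warm-up over. Flags enter the
feature records as `detected.<solver_id>`, so a tree can condition on
individual detectors.

## The synthetic problem generator

`x_i = μ + A·g(i)·s(i) + ε_i` with 1-based i; g is 1 on i ≤ L for the
constant trend and ((L−i)/L)² for the quadratic trend (decaying to 0
exactly at L, so quadratic bias vanishes continuously while constant bias
drops abruptly); s is 1 (line), sin(2πi/period) (oscillating, period 20 by
default — a few cycles inside a typical warm-up), or fresh uniform ±1
draws (random). The noise is AR(1), ε_i = ρ·ε_{i−1} + (1−ρ)·ν_i, with
ν_i uniform on ±θ% of μ and θ drawn once per series from the configured
interval. Symmetric noise is used deliberately: adding a strictly positive
"random value" would shift the true mean and destroy the exactness of the
label μ. Defaults: μ = 10, A = 5 (a 50% initial bias, large enough that
failing to truncate is clearly visible in the error), ρ as configured per
grid.

The default full-factorial grid spans bias fractions {0.1, 0.25, 0.4,
0.6}, all six (trend, shape) types, noise levels {0, 10, 25, 50}% of μ,
lengths {1000, 2000}, ρ = 0.3, 10 replications. The shipped pipeline
trains on a scaled version (length 1000 only, 5 replications → 480 series)
and tests on factor values between the training points (bias {0.15, 0.3,
0.5}, noise {5, 20, 40}%, 2 replications → 108 series); these sizes keep a
full train-and-benchmark study around two minutes on one core. Replication
seeds derive from the master seed plus a stable hash of the problem
definition, making every problem set bit-reproducible.

What the generator emulates: the level offset, decay, oscillation and
autocorrelated fluctuation patterns of simulation output during an initial
transient. What it does not: state-dependent noise variance, discreteness
of copy numbers, bistability, or transients longer than the series. The
`ssa_fixture` (exact Gillespie simulation of A + B ⇌ AB with the
deterministic equilibrium root as the truth label) covers discreteness and
state-dependent noise on one well-understood system; passing tests on
generated problems therefore support, but do not prove, performance on
real simulator output.

## Training the composition function

For each training problem the series is cut into 10 chunks and each prefix
of 1..10 chunks yields one record: the 13 features, the ten detection
flags, and the label `warmup_over` iff the prefix extends past the known
warm-up length L. Chunk boundaries are aligned with the warm-up by default
(5 chunks partition [0, L), 5 the tail) so that training prefixes mirror
the chunked protocol the deployed solver faces and the two classes are
balanced by construction; uniform whole-series chunking is available and
is the fallback when L is too short. Records from stochastic replications
of the same problem definition are averaged (features: mean; flags:
majority) before induction — single trees on raw records proved unstable
across training draws, with deployed median errors varying several-fold.

The learner is a small deterministic C4.5-style induction: binary numeric
splits chosen by information gain ratio, recursion until purity or a
minimum leaf size (3 on aggregated records), optional pessimistic pruning
with the usual confidence-bound error estimate (CF = 0.25). Leaf labeling
is cost-sensitive: a leaf declares the warm-up over only when at least 90%
of its records carry that label. The asymmetry is deliberate — a premature
declaration returns a biased estimate whose error is unbounded, while a
delayed one merely requests one more chunk. Cross-validation is grouped by
problem id so that iterations of one series never straddle folds.

The deployed SPS runs all ten baselines every iteration (select-all),
classifies the latest feature record with the tree, and on `warmup_over`
returns the unweighted mean of the baseline estimates that are *defined*
at that iteration (an undefined estimate cannot be averaged); if none is
defined it keeps requesting. The portfolio composer aggregates requests by
weight majority — the rule is unspecified in the portfolio literature
for this setting, and majority-by-weight is the natural reading. The
descriptor serializes solvers, parameters, the tree, and training metadata
(grid, master seed, per-feature value ranges) to JSON; an online-adaptation
hook exists in the solve path but is a deliberate no-op.

## Evaluation harness

The *ideal truncation point* of a problem is the d minimizing the
across-replication mean squared error of the truncated mean against the
true mean (computed with suffix sums; an O(n²) brute force serves as the
oracle in tests). Because the MSE curve is nearly flat past the true
warm-up end, its sampled argmin is noise-dominated there: with 1–3
replications it wandered hundreds of observations into the steady region,
so the benchmark computes it from 100 dedicated replications (cheap — only
generation, no solving) while solvers are scored on a separate, smaller
set of replications (3 by default).

Each series is cut into 5 chunks partitioning [0, d*) and 5 partitioning
the rest (remainders to earlier chunks, for bit-reproducibility), and fed
through the solve loop. The first defined estimate after chunk j ≤ 5 gets
signed index j − 6 (premature); after chunk 5 + m, index +m (robust, and
efficient for small m); no estimate is reported as NONE, with errors
recorded for all fired estimates including premature ones. If d* falls
outside [5, n − 5] it is clamped so the protocol remains defined.

## Known limitations

* A warm-up consisting of a *constant level shift* (constant trend, line
  shape) is, on any prefix that ends before the shift, a stationary series
  — indistinguishable from steady data under features that are
  deliberately scale- and length-invariant. No classifier over these
  inputs can refuse to fire there yet still fire on genuinely steady
  data, and with five pre-truncation chunks each offering an independent
  chance to misfire, the SPS's fraction of strictly-positive signed
  indices plateaus around 0.7–0.85 on the default test grid (the
  benchmark reports ≈ 0.77 at seed 1). Its median relative error is
  nevertheless below every individual baseline's.
* The balancing-mean baseline is structurally biased on half-and-half
  level-shift series (the counts balance at truncation 0); its estimates
  enter the equal-weight average whenever it fires, which bounds the
  composite accuracy from below.
* Detection flags double as implicit series-length signals (several
  detectors have minimum data requirements); trees may exploit this, which
  is legitimate at deployment but worth knowing when reading a tree.
* Wall-clock profiling, confidence intervals for the steady-state mean,
  and trees that select among estimators (rather than classify warm-up)
  are out of scope; the select-one composer supports the latter pattern
  but no trainer for it is provided.
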