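"""Ten baseline steady-state estimators.

Each estimator is a warm-up (initial transient) detector: given a series it
either locates a truncation point d -- the number of leading observations to
delete -- or reports that no steady state is visible yet.  All ten share one
estimate rule afterwards, the arithmetic mean of the retained suffix, so
accuracy differences between them reflect truncation quality only.

Every detector is exposed twice: as a pure function ``detect_<id>(series,
params) -> Detection`` on a full series, and as an iterative solver
(:class:`EstimatorSolver`) conforming to the :mod:`spskit.core` interface,
which requests more data until its detector fires.

Conventions shared by all detectors:

* insufficient data never raises -- it yields ``found=False``;
* a zero-variance suffix is a valid steady state, detected at the earliest
  candidate truncation (constant trajectories are steady);
* ties are broken toward the smallest qualifying index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .core import (
    UNDEFINED,
    IteratedProblem,
    Request,
    SolverState,
    TimeSeries,
    as_series,
    materialize_series,
)

_EPS = 1e-12


@dataclass(frozen=True)
class Detection:
    """Outcome of a warm-up detector.

    ``truncation`` is the count of deleted leading observations (0-based);
    it is only meaningful when ``found``.  ``statistic`` carries the
    detector's diagnostic value (MSER statistic, p-value, ...).
    """

    found: bool
    truncation: Optional[int] = None
    statistic: float = float("nan")


@dataclass(frozen=True)
class EstimatorParams:
    """Default parameters for all ten detectors, overridable via config.

    Values are typical of the simulation output-analysis literature and are
    fixed so results are reproducible.
    """

    mser_min_retained: int = 10
    euclid_window: int = 10
    euclid_run: int = 3
    euclid_eps: float = 0.1
    gof_batch: int = 25
    gof_alpha: float = 0.05
    balancing_delta: float = 0.02
    running_window: int = 25
    running_eps: float = 0.01
    batch_size: int = 25
    batch_groups: int = 5
    batch_alpha: float = 0.05
    crossing_count: int = 25
    stop_crossing_len: int = 50
    schruben_alpha: float = 0.05
    schruben_batches: int = 10
    window_len: int = 100
    window_run: int = 5
    window_theta: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mser_min_retained", "euclid_window", "gof_batch", "running_window",
                     "batch_size", "stop_crossing_len", "window_len"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("gof_alpha", "batch_alpha", "schruben_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("euclid_eps", "balancing_delta", "running_eps", "window_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("euclid_run", "batch_groups", "crossing_count", "schruben_batches",
                     "window_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


DEFAULT_PARAMS = EstimatorParams()

NOT_FOUND = Detection(found=False)


def _suffix_sums(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Suffix sums of x and x**2: s1[d] = sum(x[d:]), s2[d] = sum(x[d:]**2)."""
    s1 = np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])
    s2 = np.concatenate([np.cumsum((x * x)[::-1])[::-1], [0.0]])
    return s1[:-1], s2[:-1]


def _is_constant(x: np.ndarray) -> bool:
    return x.size > 0 and np.all(x == x[0])


#: No detector reports a steady state from fewer than this many points.
MIN_SERIES_LENGTH = 10


def _prologue(x: np.ndarray) -> Optional[Detection]:
    """Conventions shared by every detector, applied before its own rule.

    Below the global minimum length nothing is detected; a zero-variance
    series of sufficient length is a valid steady state, detected at d=0
    (this outranks detector-specific length requirements: a constant series
    needs no warm-up removal however the detector would batch it).
    """
    if x.size < MIN_SERIES_LENGTH:
        return Detection(found=False)
    if _is_constant(x):
        return Detection(found=True, truncation=0, statistic=0.0)
    return None


# ---------------------------------------------------------------------------
# 1. MSER

def detect_mser(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Marginal Standard Error Rule.

    MSER(d) = (1/(n-d)^2) * sum_{i>d} (x_i - mean(x_{d+1..n}))^2, minimized
    over 0 <= d <= n - m_min; the warm-up end is accepted only if the
    minimizing d lies in the first half of the series.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    n = x.size
    if n < params.mser_min_retained:
        return NOT_FOUND
    d_max = n - params.mser_min_retained  # inclusive
    s1, s2 = _suffix_sums(x)
    lengths = n - np.arange(d_max + 1)
    ss = np.maximum(s2[: d_max + 1] - s1[: d_max + 1] ** 2 / lengths, 0.0)
    mser = ss / lengths**2
    d_star = int(np.argmin(mser))  # argmin takes the smallest index on ties
    if d_star >= n / 2:
        return Detection(found=False, statistic=float(mser[d_star]))
    return Detection(found=True, truncation=d_star, statistic=float(mser[d_star]))


# ---------------------------------------------------------------------------
# 2. Euclidean distance

def detect_euclidean(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Normalized-vector distance rule.

    The series is cut into consecutive vectors of length w.  Each vector is
    scaled by the Euclidean norm of the *last* vector (the trailing level is
    the best available proxy for the steady level) and compared to the
    all-ones direction; steady data yields vectors close to it.  Detection
    requires the final k vectors to qualify; the truncation is the start of
    the contiguous qualifying run that ends at the last vector.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    w, k, eps = params.euclid_window, params.euclid_run, params.euclid_eps
    n = x.size
    n_vec = n // w
    if n < w * k or n_vec < k:
        return NOT_FOUND
    vectors = x[: n_vec * w].reshape(n_vec, w)
    ref = float(np.linalg.norm(vectors[-1]))
    unit = np.full(w, 1.0 / np.sqrt(w))
    if ref == 0.0:
        # all-zero trailing level: a vector qualifies iff it is all zeros too
        dists = np.where(np.all(vectors == 0.0, axis=1), 0.0, np.inf)
    else:
        dists = np.linalg.norm(vectors / ref - unit, axis=1)
    qualifies = dists <= eps
    if not np.all(qualifies[-k:]):
        return Detection(found=False, statistic=float(dists[-k:].max()))
    start = n_vec - 1
    while start > 0 and qualifies[start - 1]:
        start -= 1
    return Detection(found=True, truncation=start * w, statistic=float(dists[-k:].max()))


# ---------------------------------------------------------------------------
# 3. Goodness of fit

def detect_goodness_of_fit(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Chi-square above/below-mean batch homogeneity rule.

    For each candidate truncation d (scanned in batch-size steps), the
    retained suffix is split into batches; within each batch the counts of
    values above and below the suffix mean are compared to the even split
    expected in steady state via a chi-square statistic with b-1 degrees of
    freedom.  The smallest d that is not rejected at level alpha wins.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    B, alpha = params.gof_batch, params.gof_alpha
    n = x.size
    for d in range(0, n - 2 * B + 1, B):
        suffix = x[d:]
        b = suffix.size // B
        used = suffix[: b * B]
        if _is_constant(used):
            return Detection(found=True, truncation=d, statistic=1.0)
        mean = used.mean()
        batches = used.reshape(b, B)
        above = np.sum(batches > mean, axis=1)
        below = np.sum(batches < mean, axis=1)
        expected = B / 2.0
        chi2 = float(np.sum((above - expected) ** 2 / expected + (below - expected) ** 2 / expected))
        p = float(stats.chi2.sf(chi2, df=b - 1))
        if p >= alpha:
            return Detection(found=True, truncation=d, statistic=p)
    return NOT_FOUND


# ---------------------------------------------------------------------------
# 4. Balancing mean

def detect_balancing_mean(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Counts of values above vs. below the suffix mean must balance.

    Found at the smallest d <= n/2 whose suffix has |#above - #below| <=
    delta * (n - d); values equal to the mean count to neither side.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    delta = params.balancing_delta
    n = x.size
    if n == 0:
        return NOT_FOUND
    for d in range(0, n // 2 + 1):
        suffix = x[d:]
        mean = suffix.mean()
        diff = abs(int(np.sum(suffix > mean)) - int(np.sum(suffix < mean)))
        if diff <= delta * suffix.size:
            return Detection(found=True, truncation=d, statistic=diff / suffix.size)
    return NOT_FOUND


# ---------------------------------------------------------------------------
# 5. Running mean

def detect_running_mean(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Change in the running mean falls below a threshold.

    With running means m_i of the first i observations, detection occurs at
    the smallest i >= k whose last k increments |m_j - m_{j-1}|, relative to
    |m_i|, all fall below eps; the truncation is d = i - k.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    k, eps = params.running_window, params.running_eps
    n = x.size
    if n < k + 1:
        return NOT_FOUND
    m = np.cumsum(x) / np.arange(1, n + 1)
    inc = np.abs(np.diff(m))  # inc[j-2] = |m_j - m_{j-1}| (1-based j >= 2)
    for i in range(k, n + 1):  # 1-based index into the series
        lo = max(2, i - k + 1)
        window = inc[lo - 2 : i - 1]
        if window.size == 0:
            continue
        ratio = float(window.max()) / (abs(m[i - 1]) + _EPS)
        if ratio <= eps:
            return Detection(found=True, truncation=i - k, statistic=ratio)
    return NOT_FOUND


# ---------------------------------------------------------------------------
# 6. Batch means

def detect_batch_mean(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Variance homogeneity of early vs. late batch means (two-sided F-test).

    After dropping d leading observations (d scanned in steps of the batch
    size parameter), the whole remainder is cut into 2g equal batches;
    steady data should give the first g and last g batch means
    statistically equal variances.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    m, g, alpha = params.batch_size, params.batch_groups, params.batch_alpha
    n = x.size
    for d in range(0, n - 4 * g + 1, m):
        suffix = x[d:]
        if _is_constant(suffix):
            return Detection(found=True, truncation=d, statistic=1.0)
        bsize = suffix.size // (2 * g)
        if bsize < 2:
            break
        means = suffix[: 2 * g * bsize].reshape(2 * g, bsize).mean(axis=1)
        var_a = float(np.var(means[:g], ddof=1))
        var_b = float(np.var(means[g:], ddof=1))
        if var_a == 0.0 and var_b == 0.0:
            # flat within both groups: steady only if they sit at one level
            if means[0] == means[-1]:
                return Detection(found=True, truncation=d, statistic=1.0)
            continue
        if var_a == 0.0 or var_b == 0.0:
            continue  # p = 0, reject
        f = var_a / var_b
        p = 2.0 * min(stats.f.cdf(f, g - 1, g - 1), stats.f.sf(f, g - 1, g - 1))
        if p >= alpha:
            return Detection(found=True, truncation=d, statistic=float(p))
    return NOT_FOUND


# ---------------------------------------------------------------------------
# crossing helpers

def _cross_positions(x: np.ndarray) -> np.ndarray:
    """0-based indices where the series crosses its running mean.

    A cross at i is a sign change of (x_i - m_i) relative to the previous
    observation's deviation, zeros inheriting the previous sign.
    """
    n = x.size
    if n <= 1:
        return np.empty(0, dtype=int)
    m = np.cumsum(x) / np.arange(1, n + 1)
    signs = np.sign(x - m)
    # forward-fill zero signs with the previous non-zero sign
    nz = signs != 0
    idx = np.where(nz, np.arange(n), -1)
    ffill = np.maximum.accumulate(idx)
    filled = np.where(ffill >= 0, signs[np.maximum(ffill, 0)], 0.0)
    prev, cur = filled[:-1], filled[1:]
    crossed = (prev != 0) & (cur != 0) & (prev != cur)
    return np.nonzero(crossed)[0] + 1


# ---------------------------------------------------------------------------
# 7. Crossing mean

def detect_crossing_mean(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Warm-up ends once the series has crossed its running mean c times."""
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    c = params.crossing_count
    crosses = _cross_positions(x)
    if crosses.size < c:
        return Detection(found=False, statistic=float(crosses.size))
    return Detection(found=True, truncation=int(crosses[c - 1]), statistic=float(c))


# ---------------------------------------------------------------------------
# 8. Stop-crossing mean

def detect_stop_crossing_mean(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Warm-up ends when no running-mean cross occurred for L observations."""
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    L = params.stop_crossing_len
    n = x.size
    if n < L:
        return NOT_FOUND
    crosses = _cross_positions(x)
    if crosses.size == 0:
        return Detection(found=True, truncation=0, statistic=0.0)
    last = int(crosses[-1])
    if last >= n - L:  # a cross inside the most recent L observations
        return Detection(found=False, statistic=float(n - 1 - last))
    return Detection(found=True, truncation=last, statistic=float(n - 1 - last))


# ---------------------------------------------------------------------------
# 9. Schruben's test

def detect_schruben(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Schruben's initialization-bias test on successively truncated suffixes.

    The partial sums S_k = k * (mean of all - mean of first k) of a
    stationary suffix behave like a Brownian bridge; their sum, standardized
    by a batch-means estimate of the variance parameter, is referred to a
    t distribution.  The variance parameter is estimated from the *second
    half* of the suffix, which initialization bias is assumed not to reach
    -- estimating it from the full suffix would let the bias inflate the
    variance and mask itself.  Truncations are scanned in steps of ~10% of
    the series length; the first suffix where the no-bias null is *not*
    rejected wins.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    alpha, nb = params.schruben_alpha, params.schruben_batches
    n = x.size
    if n == 0:
        return NOT_FOUND
    step = max(1, int(np.ceil(n / 10)))
    d = 0
    while n - d >= 2 * nb:
        y = x[d:]
        m_len = y.size
        if _is_constant(y):
            return Detection(found=True, truncation=d, statistic=1.0)
        cum = np.cumsum(y)
        k = np.arange(1, m_len + 1)
        s = k * y.mean() - cum
        area = float(s.sum())
        half = y[m_len - m_len // 2 :]
        bs = half.size // nb
        if bs == 0:
            d += step
            continue
        bmeans = half[: nb * bs].reshape(nb, bs).mean(axis=1)
        var_hat = bs * float(np.var(bmeans, ddof=1))
        if var_hat == 0.0:
            # flat tail: accept only a bias-free (flat) bridge
            if abs(area) < _EPS:
                return Detection(found=True, truncation=d, statistic=1.0)
            d += step
            continue
        z = area / np.sqrt(var_hat * m_len * (m_len**2 - 1) / 12.0)
        p = 2.0 * float(stats.t.sf(abs(z), df=nb - 1))
        if p >= alpha:
            return Detection(found=True, truncation=d, statistic=p)
        d += step
    return NOT_FOUND


# ---------------------------------------------------------------------------
# 10. Moving window

def detect_moving_window(series: TimeSeries, params: EstimatorParams = DEFAULT_PARAMS) -> Detection:
    """Stability of consecutive moving-window means.

    Windows of length w slide over the series; detection occurs at the first
    run of k consecutive window means whose standard deviation, relative to
    the series value range, falls below theta.  The truncation is the start
    of the first window in that run.
    """
    x = as_series(series)
    if (early := _prologue(x)) is not None:
        return early
    w, k, theta = params.window_len, params.window_run, params.window_theta
    n = x.size
    if n < w + k:
        return NOT_FOUND
    value_range = float(x.max() - x.min())
    if value_range == 0.0:
        return Detection(found=True, truncation=0, statistic=0.0)
    cum = np.concatenate([[0.0], np.cumsum(x)])
    wmeans = (cum[w:] - cum[:-w]) / w  # wmeans[i] = mean of x[i:i+w]
    runs = np.lib.stride_tricks.sliding_window_view(wmeans, k)
    ratios = runs.std(axis=1, ddof=1) / value_range if k > 1 else np.zeros(runs.shape[0])
    ok = np.nonzero(ratios <= theta)[0]
    if ok.size == 0:
        return Detection(found=False, statistic=float(ratios.min()))
    start = int(ok[0])
    return Detection(found=True, truncation=start, statistic=float(ratios[start]))


# ---------------------------------------------------------------------------
# estimate + solver wrapper

def estimate_mean(series: TimeSeries, truncation: int) -> float:
    """Arithmetic mean of the post-truncation suffix x_{d+1..n}."""
    x = as_series(series)
    if not 0 <= truncation < x.size:
        raise ValueError(f"empty suffix: truncation {truncation} of series length {x.size}")
    return float(x[truncation:].mean())


DETECTORS: dict[str, Callable[[TimeSeries, EstimatorParams], Detection]] = {
    "mser": detect_mser,
    "euclidean": detect_euclidean,
    "gof": detect_goodness_of_fit,
    "balancing": detect_balancing_mean,
    "running_mean": detect_running_mean,
    "batch_mean": detect_batch_mean,
    "crossing": detect_crossing_mean,
    "stop_crossing": detect_stop_crossing_mean,
    "schruben": detect_schruben,
    "moving_window": detect_moving_window,
}

ESTIMATOR_IDS = tuple(DETECTORS)


def solver_step(
    estimator_id: str,
    problem: IteratedProblem,
    state: SolverState,
    params: EstimatorParams = DEFAULT_PARAMS,
) -> SolverState:
    """One iteration of an estimator as an iterative solver.

    Materializes the series delivered so far and runs the detector; on a
    detection the successor state carries the suffix-mean estimate and stops
    requesting, otherwise it requests more data.  The payload caches the
    last detection keyed by series length, so re-solving an unchanged
    problem is free.
    """
    if estimator_id not in DETECTORS:
        raise KeyError(
            f"unknown estimator {estimator_id!r}; registered: {', '.join(ESTIMATOR_IDS)}"
        )
    x = materialize_series(problem)
    cache = state.payload if isinstance(state.payload, dict) else {}
    if cache.get("n") == x.size and "detection" in cache:
        detection = cache["detection"]
    else:
        detection = DETECTORS[estimator_id](x, params)
    payload = {"n": x.size, "detection": detection}
    if detection.found and x.size > 0:
        return SolverState(
            payload=payload,
            request=Request(more_data=False),
            result=estimate_mean(x, detection.truncation),
        )
    return SolverState(payload=payload, request=Request(more_data=True), result=UNDEFINED)


class EstimatorSolver:
    """A registered baseline estimator as an iterative problem solver."""

    def __init__(self, estimator_id: str, params: EstimatorParams = DEFAULT_PARAMS):
        if estimator_id not in DETECTORS:
            raise KeyError(
                f"unknown estimator {estimator_id!r}; registered: {', '.join(ESTIMATOR_IDS)}"
            )
        self.estimator_id = estimator_id
        self.params = params

    def initial_state(self) -> SolverState:
        return SolverState()

    def solve(self, problem: IteratedProblem, state: SolverState) -> SolverState:
        return solver_step(self.estimator_id, problem, state, self.params)

    def __repr__(self) -> str:  # pragma: no cover
        return f"EstimatorSolver({self.estimator_id!r})"
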