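"""Problem and state feature extractors.

The feature vector characterizes the two aspects that matter for warm-up
detection on a trajectory: the amount of noise and the shape of the
initialization bias.  Six features are computed on the raw series and seven
on an exponentially smoothed trend curve of it (the maximum absolute
distance to the mean is informative on the trend curve but overfits on the
raw series, so its raw variant is dropped), giving 13 features in total.

Count features are divided by the series length and distance features by
the value range, so vectors are comparable across series of different
lengths and scales.

The single state feature extractor, :func:`detection_flag`, reports whether
a solver has detected the end of the warm-up phase (its pending request is
the complement of that).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.stats.diagnostic import acorr_ljungbox

from .core import IteratedProblem, SolverState, TimeSeries, as_series, materialize_series

#: Fixed order of the 13 features.
FEATURE_NAMES: tuple[str, ...] = (
    "frac_above",
    "frac_below",
    "frac_diff",
    "max_pos_dist",
    "max_neg_dist",
    "portmanteau",
    "t_frac_above",
    "t_frac_below",
    "t_frac_diff",
    "t_max_pos_dist",
    "t_max_neg_dist",
    "t_max_abs_dist",
    "t_portmanteau",
)


@dataclass(frozen=True)
class FeatureVector:
    frac_above: float
    frac_below: float
    frac_diff: float
    max_pos_dist: float
    max_neg_dist: float
    portmanteau: float
    t_frac_above: float
    t_frac_below: float
    t_frac_diff: float
    t_max_pos_dist: float
    t_max_neg_dist: float
    t_max_abs_dist: float
    t_portmanteau: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def smooth_exponential(series: TimeSeries, alpha: float) -> TimeSeries:
    """Exponential smoothing: s_1 = x_1, s_i = alpha*x_i + (1-alpha)*s_{i-1}."""
    if not 0 < alpha <= 1:
        raise ValueError(f"smoothing factor must lie in (0, 1], got {alpha}")
    x = as_series(series)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    # one-pole IIR filter with the initial condition s_1 = x_1
    zi = np.array([(1 - alpha) * x[0]])
    smoothed, _ = signal.lfilter([alpha], [1.0, alpha - 1.0], x, zi=zi)
    return smoothed


def portmanteau_q(series: TimeSeries, lags: int) -> float:
    """Box-Pierce portmanteau statistic Q = n * sum of squared autocorrelations.

    An aggregate measure of autocorrelation over the first ``lags`` lags; a
    zero-variance series has no defined autocorrelation and returns 0 by
    convention.
    """
    x = as_series(series)
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if x.size <= lags:
        raise ValueError(f"series of length {x.size} too short for {lags} lags")
    if np.all(x == x[0]):
        return 0.0
    table = acorr_ljungbox(x, lags=[lags], boxpierce=True)
    return float(table["bp_stat"].iloc[0])


def _half_features(x: np.ndarray, lags: int) -> tuple[float, ...]:
    """(frac_above, frac_below, frac_diff, max_pos, max_neg, max_abs, Q) for one curve."""
    n = x.size
    mean = x.mean()
    above = int(np.sum(x > mean))
    below = int(np.sum(x < mean))
    value_range = float(x.max() - x.min())
    if value_range == 0.0:
        return (above / n, below / n, (above - below) / n, 0.0, 0.0, 0.0, 0.0)
    dev = x - mean
    max_pos = float(dev.max()) / value_range
    max_neg = float(-dev.min()) / value_range
    max_abs = float(np.abs(dev).max()) / value_range
    h = min(lags, n - 1)
    q = portmanteau_q(x, h) / value_range if h >= 1 else 0.0
    return (above / n, below / n, (above - below) / n, max_pos, max_neg, max_abs, q)


def extract_problem_features(
    problem: IteratedProblem | TimeSeries,
    alpha: float = 0.1,
    lags: int = 10,
) -> FeatureVector:
    """The 13-dimensional problem feature vector.

    Accepts either an iterated problem (whose series is materialized first)
    or a plain series.  Count features are normalized by the series length,
    distance and portmanteau features by the value range of the curve they
    are computed on; a degenerate (zero-range) curve yields zeros for all
    range-normalized features.
    """
    if isinstance(problem, IteratedProblem):
        x = materialize_series(problem)
    else:
        x = as_series(problem)
    if x.size == 0:
        raise ValueError("cannot extract features from an empty series")
    raw = _half_features(x, lags)
    trend = _half_features(smooth_exponential(x, alpha), lags)
    return FeatureVector(
        frac_above=raw[0], frac_below=raw[1], frac_diff=raw[2],
        max_pos_dist=raw[3], max_neg_dist=raw[4], portmanteau=raw[6],
        t_frac_above=trend[0], t_frac_below=trend[1], t_frac_diff=trend[2],
        t_max_pos_dist=trend[3], t_max_neg_dist=trend[4],
        t_max_abs_dist=trend[5], t_portmanteau=trend[6],
    )


def detection_flag(state: SolverState) -> bool:
    """True iff the solver detected the end of the warm-up phase.

    Equivalently: the state's pending request for more data is False.  A
    fresh, never-solved state requests data by construction, so the flag is
    False for it.
    """
    return not state.request.more_data
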