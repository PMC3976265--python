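"""Evaluation harness: ideal truncation, chunk protocol, and benchmarks.

Estimators are judged on three axes.  *Accuracy*: the relative distance
between the estimated and the true steady-state mean.  *Robustness*:
whether the first estimate appears only after the ideal truncation point.
*Data efficiency*: how few chunks past that point are needed.

The ideal truncation point of a problem is the truncation d minimizing the
across-replication mean squared error of the truncated mean against the
true steady-state mean (the replicated-MSE rule; exact here because the
generator knows the true mean).  Each series is then cut into k_pre chunks
covering the warm-up (up to the ideal truncation point) and k_post chunks
covering the steady part, and fed chunk by chunk through the iterative
solve loop.  The chunk index at which the first estimate appears is
reported signed: -k_pre..-1 before the truncation point (premature),
+1..+k_post after (robust), NONE if no estimate was ever produced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import UNDEFINED, ChunkedSource, IteratedProblem, Solver, TimeSeries, as_series
from .estimators import DEFAULT_PARAMS, EstimatorParams, EstimatorSolver
from .synthgen import LabeledSeries, generate_series


@dataclass(frozen=True)
class EvalProtocol:
    """Chunking and repetition plan for a benchmark run.

    ``truncation_replications`` controls how many fresh replications feed
    the ideal-truncation computation; the replicated-MSE curve is flat and
    noisy in the steady region, so with too few replications its argmin
    wanders far from the true end of the warm-up.
    """

    k_pre: int = 5
    k_post: int = 5
    repetitions: int = 3
    truncation_replications: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_pre < 1 or self.k_post < 1:
            raise ValueError("k_pre and k_post must be >= 1")
        if self.repetitions < 1 or self.truncation_replications < 1:
            raise ValueError("repetition counts must be >= 1")


@dataclass(frozen=True)
class EvalResult:
    estimator_id: str
    problem_id: str
    replication: int
    chunk_index: Optional[int]  # signed; None = no estimate produced
    relative_error: Optional[float]
    estimate: Optional[float]


def ideal_truncation(replications: Sequence[TimeSeries], true_mean: float) -> int:
    """Truncation minimizing the across-replication MSE of the suffix mean.

    argmin over d in [0, n-1] of mean_r (mean(x_r[d:]) - mu)^2, smallest d
    on ties.  Implemented with suffix sums; equivalent to the O(n^2) direct
    computation.
    """
    arrays = [as_series(r) for r in replications]
    if not arrays:
        raise ValueError("need at least one replication")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("replications must have equal lengths")
    if n == 0:
        raise ValueError("replications are empty")
    stacked = np.vstack(arrays)
    suffix_sums = np.cumsum(stacked[:, ::-1], axis=1)[:, ::-1]
    lengths = n - np.arange(n)
    suffix_means = suffix_sums / lengths
    mse = np.mean((suffix_means - true_mean) ** 2, axis=0)
    return int(np.argmin(mse))


def chunk_series(series: TimeSeries, truncation: int, protocol: EvalProtocol) -> list[TimeSeries]:
    """k_pre chunks partitioning the warm-up + k_post partitioning the rest.

    Both partitions are as equal as possible, remainders going to earlier
    chunks; concatenating the chunks reproduces the series exactly.
    """
    x = as_series(series)
    n = x.size
    if truncation < protocol.k_pre or n - truncation < protocol.k_post:
        raise ValueError(
            f"series too short to chunk: n={n}, truncation={truncation}, "
            f"protocol {protocol.k_pre}+{protocol.k_post}"
        )
    pre = np.array_split(x[:truncation], protocol.k_pre)
    post = np.array_split(x[truncation:], protocol.k_post)
    return pre + post


def evaluate_estimator(
    solver: Solver,
    labeled: LabeledSeries,
    protocol: EvalProtocol,
    truncation: int,
    estimator_id: str = "",
) -> EvalResult:
    """Feed the chunked series through the solve loop and score the outcome."""
    chunks = chunk_series(labeled.values, truncation, protocol)
    total = protocol.k_pre + protocol.k_post
    problem = IteratedProblem(initial=chunks[0])
    source = ChunkedSource(chunks[1:])
    state = solver.initial_state()
    estimate = UNDEFINED
    consumed = 1
    for _ in range(total):
        state = solver.solve(problem, state)
        if not state.request.more_data:
            estimate = state.result
            break
        segment = source.next_segment(state.request)
        if segment is None:
            break
        problem.append_answer(state.request, segment)
        consumed += 1
    if estimate is UNDEFINED:
        return EvalResult(estimator_id, labeled.problem_id, labeled.replication,
                          None, None, None)
    if consumed <= protocol.k_pre:
        index = consumed - protocol.k_pre - 1  # -k_pre .. -1
    else:
        index = consumed - protocol.k_pre  # +1 .. +k_post
    rel_err = abs(estimate - labeled.true_mean) / abs(labeled.true_mean)
    return EvalResult(estimator_id, labeled.problem_id, labeled.replication,
                      index, rel_err, estimate)


def _replicate(
    labeled: LabeledSeries, protocol: EvalProtocol, count: int, salt: int = 0
) -> list[LabeledSeries]:
    """Fresh stochastic replications of one problem, seeds derived per repetition."""
    reps = []
    for rep in range(count):
        seed = (
            labeled.spec.seed + 1_000_003 * (rep + 1) + 7_919 * salt + protocol.seed
        ) % (2**31 - 1)
        spec = replace(labeled.spec, seed=seed)
        reps.append(replace(generate_series(spec),
                            problem_id=labeled.problem_id, replication=rep))
    return reps


def benchmark(
    solvers: dict[str, Solver],
    problems: Sequence[LabeledSeries],
    protocol: EvalProtocol = EvalProtocol(),
    regenerate: bool = True,
) -> pd.DataFrame:
    """Evaluate a set of solvers over a problem set.

    For each problem, ``protocol.repetitions`` replications are generated
    (or the problem itself reused when ``regenerate`` is False), the ideal
    truncation point is computed across the replications, and every solver
    is scored on every replication.  Returns one row per (estimator,
    problem) with repetition-averaged relative error, mean signed chunk
    index, and the fractions of NONE and premature outcomes.
    """
    rows = []
    for labeled in problems:
        if regenerate:
            reps = _replicate(labeled, protocol, protocol.repetitions)
            trunc_reps = _replicate(
                labeled, protocol, protocol.truncation_replications, salt=1
            )
        else:
            reps = trunc_reps = [labeled]
        trunc = ideal_truncation([r.values for r in trunc_reps], labeled.true_mean)
        n = labeled.values.size
        trunc = int(np.clip(trunc, protocol.k_pre, n - protocol.k_post))
        for est_id, solver in solvers.items():
            results = [
                evaluate_estimator(solver, rep, protocol, trunc, est_id)
                for rep in reps
            ]
            errors = [r.relative_error for r in results if r.relative_error is not None]
            indices = [r.chunk_index for r in results if r.chunk_index is not None]
            rows.append({
                "estimator": est_id,
                "problem": labeled.problem_id,
                "mean_rel_error": float(np.mean(errors)) if errors else np.nan,
                "mean_index": float(np.mean(indices)) if indices else np.nan,
                "frac_none": sum(r.chunk_index is None for r in results) / len(results),
                "frac_premature": sum(
                    r.chunk_index is not None and r.chunk_index < 0 for r in results
                ) / len(results),
            })
    return pd.DataFrame(rows)


def baseline_solvers(
    estimator_ids: Sequence[str] = None,
    params: EstimatorParams = DEFAULT_PARAMS,
) -> dict[str, Solver]:
    from .estimators import ESTIMATOR_IDS

    ids = list(estimator_ids) if estimator_ids else list(ESTIMATOR_IDS)
    return {sid: EstimatorSolver(sid, params) for sid in ids}


def plot_accuracy(table: pd.DataFrame, path) -> None:
    """Per-estimator accuracy summary on a log-scaled error axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = table.groupby("estimator")["mean_rel_error"].median().sort_values()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    floor = 1e-6
    ax.bar(summary.index, np.maximum(summary.to_numpy(), floor))
    ax.set_yscale("log")
    ax.set_ylabel("median relative error")
    ax.set_xlabel("estimator")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
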