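"""Iterative problem-solver contract and the management loop that drives it.

Steady-state estimation on simulation output is inherently iterative: an
estimator inspects the trajectory produced so far, and either returns an
estimate of the steady-state mean or requests more data points (which a
simulator, or here an :class:`AnswerSource`, appends to the series).  This
module defines the small set of types shared by every solver in the package
-- the request/result pair, the solver state triplet, the iterated problem
with its request history -- and :func:`run_solver`, the management component
that loops a solver to completion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Distinguished "no estimate produced" result.  Solvers return this while
#: they still need data, and the management loop returns it when the data
#: source is exhausted before a detection was made.
UNDEFINED = None

TimeSeries = np.ndarray


def as_series(values: Iterable[float]) -> TimeSeries:
    """Coerce ``values`` to a 1-D float array and validate finiteness."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("time series contains non-finite values")
    return arr


@dataclass(frozen=True)
class Request:
    """A solver's demand for additional observations."""

    more_data: bool


@dataclass
class SolverState:
    """The (payload, request, result) triplet carried between iterations.

    ``payload`` holds solver-specific scratch data (cached running means,
    last truncation index, ...).  The invariant maintained by every solver:
    a defined ``result`` implies ``request.more_data`` is False.
    """

    payload: Any = None
    request: Request = field(default_factory=lambda: Request(more_data=True))
    result: Optional[float] = UNDEFINED

    def __post_init__(self) -> None:
        if self.result is not UNDEFINED and self.request.more_data:
            raise ValueError("a defined result is inconsistent with a pending data request")


@dataclass
class IteratedProblem:
    """The initial series plus the append-only request/answer history."""

    initial: TimeSeries
    history: list[tuple[Request, TimeSeries]] = field(default_factory=list)

    def append_answer(self, request: Request, segment: TimeSeries) -> None:
        segment = as_series(segment)
        if segment.size == 0:
            raise ValueError("history answers must be non-empty segments")
        self.history.append((request, segment))


def materialize_series(problem: IteratedProblem) -> TimeSeries:
    """Concatenate the initial series with all answered segments, in order."""
    parts = [as_series(problem.initial)] + [seg for _, seg in problem.history]
    return np.concatenate(parts) if parts else np.empty(0)


class Solver(Protocol):
    """The problem-solver interface: a single iterative ``solve`` function."""

    def initial_state(self) -> SolverState: ...

    def solve(self, problem: IteratedProblem, state: SolverState) -> SolverState: ...


class AnswerSource:
    """Delivers consecutive, disjoint segments of one underlying trajectory.

    ``ChunkedSource`` below is the concrete implementation used throughout;
    the base class documents the contract: each call to :meth:`next_segment`
    yields the next segment or ``None`` once the trajectory is exhausted.
    """

    def next_segment(self, request: Request) -> Optional[TimeSeries]:
        raise NotImplementedError


class ChunkedSource(AnswerSource):
    """An :class:`AnswerSource` over a pre-computed list of segments."""

    def __init__(self, segments: Sequence[TimeSeries]):
        self._segments = [as_series(s) for s in segments]
        self._cursor = 0

    def next_segment(self, request: Request) -> Optional[TimeSeries]:
        if self._cursor >= len(self._segments):
            return None
        seg = self._segments[self._cursor]
        self._cursor += 1
        return seg


def run_solver(
    solver: Solver,
    p0: TimeSeries,
    source: Optional[AnswerSource] = None,
    max_iterations: int = 1000,
) -> Optional[float]:
    """Drive ``solver`` until it produces a result or data runs out.

    Repeatedly calls ``solver.solve``; every granted request appends one
    answer segment to the problem history.  Returns the solver's estimate,
    or :data:`UNDEFINED` when the source is exhausted or ``max_iterations``
    solve calls have been made without a detection.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    problem = IteratedProblem(initial=as_series(p0))
    state = solver.initial_state()
    for iteration in range(max_iterations):
        try:
            state = solver.solve(problem, state)
        except Exception as exc:  # pragma: no cover - defensive context
            raise RuntimeError(
                f"solver failed at iteration {iteration + 1} "
                f"(series length {materialize_series(problem).size})"
            ) from exc
        logger.debug(
            "iteration %d: more_data=%s result_defined=%s",
            iteration + 1, state.request.more_data, state.result is not UNDEFINED,
        )
        if not state.request.more_data:
            return state.result
        segment = None if source is None else source.next_segment(state.request)
        if segment is None:
            return UNDEFINED
        problem.append_answer(state.request, segment)
    return UNDEFINED


# ---------------------------------------------------------------------------
# CSV interchange

def read_series_csv(path) -> TimeSeries:
    """Read a single-column ``value`` CSV; a leading ``time`` column is ignored."""
    df = pd.read_csv(path)
    if "value" in df.columns:
        col = df["value"]
    elif df.shape[1] == 1:
        col = df.iloc[:, 0]
    else:
        raise ValueError(f"{path}: expected a 'value' column, found {list(df.columns)}")
    return as_series(col.to_numpy())


def write_series_csv(path, series: TimeSeries) -> None:
    pd.DataFrame({"value": as_series(series)}).to_csv(path, index=False)


# Shared reference fixtures: a constant trajectory, a step (warm-up at a
# higher level), and a too-short constant.
CONST100: TimeSeries = np.full(100, 10.0)
STEP: TimeSeries = np.concatenate([np.full(50, 20.0), np.full(150, 10.0)])
SHORT5: TimeSeries = np.full(5, 10.0)
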