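"""The synthetic problem solver (SPS).

An SPS is a composite solver built from (i) a non-empty ordered set of
baseline solvers, (ii) problem and state feature extractors, (iii) a
selection function choosing which baseline solvers run this iteration, and
(iv) a composition function turning the feature history and baseline states
into the composite result and request.  The SPS itself conforms to the same
iterative solve interface as its members, so SPS instances can be nested.

One solve iteration: extract problem features; select solvers; step the
selected solvers (unselected states are untouched); extract state features
from the successor states; append everything to the feature history; let
the composer produce (result, request).

Three composers realize the classic composition schemes: selecting a single
solver (algorithm selection), a weighted portfolio, and a decision-tree
ensemble that classifies whether the warm-up phase is over and, if so,
averages the defined baseline estimates with equal weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np

from .core import UNDEFINED, IteratedProblem, Request, SolverState, materialize_series
from .estimators import DEFAULT_PARAMS, EstimatorParams, solver_step
from .features import detection_flag, extract_problem_features

WARMUP_OVER = "warmup_over"
WARMUP_NOT_OVER = "warmup_not_over"


# ---------------------------------------------------------------------------
# Decision trees

@dataclass(frozen=True)
class TreeNode:
    """A decision-tree node: either a leaf (``label``) or an internal split.

    Internal nodes route feature <= threshold to ``left`` and > to ``right``.
    Feature names are drawn from the 13 problem features plus the flattened
    per-solver detection flags (``detected.<solver_id>``).
    """

    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.label}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "TreeNode":
        if "class" in data:
            return cls(label=data["class"])
        return cls(
            feature=data["feature"],
            threshold=float(data["threshold"]),
            left=cls.from_dict(data["left"]),
            right=cls.from_dict(data["right"]),
        )


def tree_predict(tree: TreeNode, record: Mapping[str, float]) -> str:
    """Traverse the tree top-down on one feature record; purely functional."""
    node = tree
    while not node.is_leaf:
        if node.feature not in record:
            raise KeyError(f"feature {node.feature!r} absent from the feature record")
        value = record[node.feature]
        node = node.left if value <= node.threshold else node.right
    return node.label


# ---------------------------------------------------------------------------
# Selection functions

def select_all(history: Sequence, features: Mapping, solvers: Sequence[str]) -> list[str]:
    """Return all baseline solvers, order preserved (no selection pressure)."""
    if not solvers:
        raise ValueError("an SPS requires a non-empty solver set")
    return list(solvers)


SELECTORS = {"select_all": select_all}


# ---------------------------------------------------------------------------
# Composition functions

def _defined_results(solver_states: Mapping[str, SolverState]) -> dict[str, float]:
    return {
        sid: st.result for sid, st in solver_states.items() if st.result is not UNDEFINED
    }


def compose_tree(
    tree: TreeNode,
    history: Sequence[dict[str, float]],
    solver_states: Mapping[str, SolverState],
) -> tuple[Optional[float], Request]:
    """Decision-tree ensemble composition.

    The latest feature record is classified by the tree.  If the warm-up is
    judged over, the result is the equally weighted mean of the baseline
    estimates that are defined at this iteration; otherwise (or if no
    estimate is defined yet) more data is requested.
    """
    if not history:
        raise ValueError("compose_tree requires a non-empty feature history")
    label = tree_predict(tree, history[-1])
    if label == WARMUP_NOT_OVER:
        return UNDEFINED, Request(more_data=True)
    defined = _defined_results(solver_states)
    if not defined:
        return UNDEFINED, Request(more_data=True)
    return float(np.mean(list(defined.values()))), Request(more_data=False)


def compose_portfolio(
    weights: Mapping[str, float],
    solver_states: Mapping[str, SolverState],
) -> tuple[Optional[float], Request]:
    """Weighted-portfolio composition.

    The result is the weight-normalized mean over solvers with a defined
    estimate; more data is requested while the requesting solvers hold more
    than half the total weight.
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("portfolio weights must be non-negative")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("portfolio weights must sum to a positive value")
    requesting = sum(
        w for sid, w in weights.items() if solver_states[sid].request.more_data
    )
    request = Request(more_data=requesting > total / 2)
    defined = {
        sid: st.result
        for sid, st in solver_states.items()
        if st.result is not UNDEFINED and weights.get(sid, 0) > 0
    }
    if not defined:
        return UNDEFINED, Request(more_data=True)
    wsum = sum(weights[sid] for sid in defined)
    value = sum(weights[sid] * res for sid, res in defined.items()) / wsum
    return float(value), request


def compose_select_one(
    choice: str,
    solver_states: Mapping[str, SolverState],
) -> tuple[Optional[float], Request]:
    """Pass through the chosen solver's result and request (ASP mapping)."""
    if choice not in solver_states:
        raise KeyError(f"unknown solver {choice!r}; have {sorted(solver_states)}")
    st = solver_states[choice]
    return st.result, st.request


# ---------------------------------------------------------------------------
# SPS definition and state

@dataclass
class SPSDefinition:
    """The (solvers, problem extractors, state extractors, selector, composer) tuple."""

    solvers: list[str]
    composer: str = "tree"  # tree | portfolio | select_one
    selector: str = "select_all"
    problem_extractors: list[str] = field(default_factory=lambda: ["problem_features"])
    state_extractors: list[str] = field(default_factory=lambda: ["detected"])
    tree: Optional[TreeNode] = None
    weights: Optional[dict[str, float]] = None
    choice: Optional[str] = None
    params: EstimatorParams = field(default_factory=lambda: DEFAULT_PARAMS)
    feature_alpha: float = 0.1
    feature_lags: int = 10
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.solvers:
            raise ValueError("an SPS requires a non-empty solver set")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.composer == "tree" and self.tree is None:
            raise ValueError("tree composer requires a tree")
        if self.composer == "select_one" and self.choice not in self.solvers:
            raise ValueError("select_one composer requires a choice among the solvers")


@dataclass
class SPSState:
    """Feature history + baseline solver states + the composite (result, request)."""

    history: list[dict[str, float]]
    solver_states: dict[str, SolverState]
    request: Request = field(default_factory=lambda: Request(more_data=True))
    result: Optional[float] = UNDEFINED


def initial_sps_state(definition: SPSDefinition) -> SPSState:
    return SPSState(
        history=[],
        solver_states={sid: SolverState() for sid in definition.solvers},
    )


def _feature_record(
    definition: SPSDefinition,
    problem: IteratedProblem,
    solver_states: Mapping[str, SolverState],
) -> dict[str, float]:
    """Flatten problem features and per-solver detection flags into one record."""
    record: dict[str, float] = {}
    if "problem_features" in definition.problem_extractors:
        fv = extract_problem_features(
            problem, alpha=definition.feature_alpha, lags=definition.feature_lags
        )
        record.update(fv.as_dict())
    if "detected" in definition.state_extractors:
        for sid, st in solver_states.items():
            record[f"detected.{sid}"] = float(detection_flag(st))
    return record


def sps_solve(
    definition: SPSDefinition,
    problem: IteratedProblem,
    state: SPSState,
) -> SPSState:
    """One iteration of the synthetic problem solver."""
    series = materialize_series(problem)
    if series.size == 0:
        return SPSState(
            history=list(state.history),
            solver_states=dict(state.solver_states),
            request=Request(more_data=True),
        )
    features = (
        extract_problem_features(
            problem, alpha=definition.feature_alpha, lags=definition.feature_lags
        ).as_dict()
        if "problem_features" in definition.problem_extractors
        else {}
    )
    selected = SELECTORS[definition.selector](state.history, features, definition.solvers)
    if not selected:
        raise ValueError("selection function returned an empty solver set")
    next_states = dict(state.solver_states)
    for sid in selected:
        next_states[sid] = solver_step(sid, problem, state.solver_states[sid], definition.params)
    record = dict(features)
    if "detected" in definition.state_extractors:
        for sid, st in next_states.items():
            record[f"detected.{sid}"] = float(detection_flag(st))
    history = list(state.history) + [record]
    if definition.composer == "tree":
        result, request = compose_tree(definition.tree, history, next_states)
    elif definition.composer == "portfolio":
        weights = definition.weights or {sid: 1.0 for sid in definition.solvers}
        result, request = compose_portfolio(weights, next_states)
    elif definition.composer == "select_one":
        result, request = compose_select_one(definition.choice, next_states)
    else:
        raise ValueError(f"unknown composer {definition.composer!r}")
    # online-adaptation hook: a composer may append auxiliary answers to the
    # request history here; intentionally a no-op in this artifact
    return SPSState(history=history, solver_states=next_states, request=request, result=result)


class SyntheticSolver:
    """An SPS definition wrapped as an iterative solver (the interface of Eq. 1)."""

    def __init__(self, definition: SPSDefinition):
        self.definition = definition

    def initial_state(self) -> SPSState:
        return initial_sps_state(self.definition)

    def solve(self, problem: IteratedProblem, state: SPSState) -> SPSState:
        return sps_solve(self.definition, problem, state)


# ---------------------------------------------------------------------------
# Descriptor serialization

def definition_to_descriptor(definition: SPSDefinition) -> dict:
    """JSON-ready descriptor of a (trained) SPS instance."""
    from dataclasses import asdict

    desc: dict[str, Any] = {
        "solvers": list(definition.solvers),
        "selector": definition.selector,
        "composer": definition.composer,
        "problem_extractors": list(definition.problem_extractors),
        "state_extractors": list(definition.state_extractors),
        "params": asdict(definition.params),
        "feature_alpha": definition.feature_alpha,
        "feature_lags": definition.feature_lags,
        "metadata": dict(definition.metadata),
    }
    if definition.tree is not None:
        desc["tree"] = definition.tree.to_dict()
    if definition.weights is not None:
        desc["weights"] = dict(definition.weights)
    if definition.choice is not None:
        desc["choice"] = definition.choice
    return desc


def definition_from_descriptor(desc: Mapping) -> SPSDefinition:
    return SPSDefinition(
        solvers=list(desc["solvers"]),
        selector=desc.get("selector", "select_all"),
        composer=desc.get("composer", "tree"),
        problem_extractors=list(desc.get("problem_extractors", ["problem_features"])),
        state_extractors=list(desc.get("state_extractors", ["detected"])),
        tree=TreeNode.from_dict(desc["tree"]) if "tree" in desc else None,
        weights=dict(desc["weights"]) if "weights" in desc else None,
        choice=desc.get("choice"),
        params=EstimatorParams(**desc.get("params", {})),
        feature_alpha=desc.get("feature_alpha", 0.1),
        feature_lags=desc.get("feature_lags", 10),
        metadata=dict(desc.get("metadata", {})),
    )


def save_descriptor(definition: SPSDefinition, path) -> None:
    with open(path, "w") as fh:
        json.dump(definition_to_descriptor(definition), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_descriptor(path) -> SPSDefinition:
    with open(path) as fh:
        return definition_from_descriptor(json.load(fh))
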