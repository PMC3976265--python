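"""Training pipeline: from labeled problems to a deployable SPS descriptor.

The pipeline applies every baseline estimator to growing prefixes of each
training series (the chunked protocol), records the 13 problem features and
the per-estimator detection flags at each iteration, labels each record by
whether the prefix already extends past the known warm-up length, and
learns a decision tree that classifies "warm-up over" vs. "not over" from
features and flags.  Group-aware cross-validation (folds split by problem,
never by record) estimates the prediction error on unseen problems, and
:func:`build_sps` wraps the learned tree into a deployable SPS definition.

The tree learner is a C4.5-style induction: binary numeric splits chosen by
information gain ratio, recursion until purity or a minimum leaf size, and
optional pessimistic (confidence-bound) pruning.  It is deliberately small
and deterministic; the ``learner`` seam in :func:`cross_validate` and
:func:`learn_tree` accepts alternative learners with the same signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimators import DEFAULT_PARAMS, DETECTORS, EstimatorParams
from .features import FEATURE_NAMES, extract_problem_features
from .sps import (
    WARMUP_NOT_OVER,
    WARMUP_OVER,
    SPSDefinition,
    TreeNode,
    definition_to_descriptor,
    tree_predict,
)
from .synthgen import LabeledSeries


@dataclass(frozen=True)
class TrainingRecord:
    problem_id: str
    replication: int
    iteration: int
    features: dict[str, float]
    flags: dict[str, bool]
    label: str

    def flat(self) -> dict[str, float]:
        row = dict(self.features)
        row.update({f"detected.{sid}": float(v) for sid, v in self.flags.items()})
        return row


@dataclass(frozen=True)
class TrainingConfig:
    """Chunking and learner settings for training-data collection.

    ``chunking='warmup'`` aligns the chunk boundaries with the problem's
    known warm-up length -- the first half of the chunks partition the
    warm-up, the rest the steady tail -- mirroring the chunk protocol the
    deployed solver faces and balancing the two classes by construction.
    ``chunking='uniform'`` cuts the whole series into equal chunks instead
    (also the fallback when a series is too short to align).

    ``aggregate='mean_over_replications'`` denoises the records before tree
    induction (stochastic replications of the same problem definition are
    averaged); single trees induced on raw records are markedly less stable
    across training draws.  ``aggregate='none'`` keeps the raw records.
    """

    chunks: int = 10
    chunking: str = "warmup"
    aggregate: str = "mean_over_replications"
    min_leaf: int = 3
    confidence: float = 0.25  # pessimistic-pruning confidence factor
    prune: bool = True
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chunks < 2:
            raise ValueError("chunks must be >= 2")
        if self.chunking not in ("warmup", "uniform"):
            raise ValueError(f"unknown chunking mode {self.chunking!r}")
        if self.aggregate not in ("none", "mean_over_replications"):
            raise ValueError(f"unknown aggregation mode {self.aggregate!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")


@dataclass(frozen=True)
class LearnerParams:
    """Induction knobs.

    ``over_purity`` makes the leaf labeling cost-sensitive: a leaf declares
    the warm-up over only when at least that fraction of its records are
    labeled over.  A premature declaration returns a biased estimate while
    a delayed one merely requests one more chunk, so the two errors carry
    very different costs; 0.9 encodes that asymmetry.
    """

    min_leaf: int = 10
    confidence: float = 0.25
    prune: bool = True
    over_purity: float = 0.9


# ---------------------------------------------------------------------------
# Data collection

def collect_training_data(
    problems: Sequence[LabeledSeries],
    estimator_ids: Sequence[str] = tuple(DETECTORS),
    config: TrainingConfig = TrainingConfig(),
    params: EstimatorParams = DEFAULT_PARAMS,
    feature_alpha: float = 0.1,
    feature_lags: int = 10,
) -> list[TrainingRecord]:
    """One record per (problem, iteration): features, flags, warm-up label.

    Iteration i sees the prefix made of the first i of ``config.chunks``
    chunks; the label is ``warmup_over`` iff that prefix is longer than the
    problem's true warm-up length.
    """
    records: list[TrainingRecord] = []
    for labeled in problems:
        x = labeled.values
        if x.size < config.chunks:
            raise ValueError(
                f"series of length {x.size} cannot be cut into {config.chunks} non-empty chunks"
            )
        k_pre = config.chunks // 2
        L = labeled.warmup_length
        if (
            config.chunking == "warmup"
            and L >= k_pre
            and x.size - L >= config.chunks - k_pre
        ):
            bounds = np.concatenate([
                np.cumsum([c.size for c in np.array_split(x[:L], k_pre)]),
                L + np.cumsum([c.size for c in np.array_split(x[L:], config.chunks - k_pre)]),
            ])
        else:
            bounds = np.cumsum([c.size for c in np.array_split(x, config.chunks)])
        for iteration, end in enumerate(bounds, start=1):
            prefix = x[:end]
            fv = extract_problem_features(prefix, alpha=feature_alpha, lags=feature_lags)
            flags = {
                sid: DETECTORS[sid](prefix, params).found for sid in estimator_ids
            }
            label = WARMUP_OVER if end > labeled.warmup_length else WARMUP_NOT_OVER
            records.append(
                TrainingRecord(
                    problem_id=labeled.problem_id or f"series_seed{labeled.spec.seed}",
                    replication=labeled.replication,
                    iteration=iteration,
                    features=fv.as_dict(),
                    flags=flags,
                    label=label,
                )
            )
    return records


def records_to_frame(records: Sequence[TrainingRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"problem_id": r.problem_id, "replication": r.replication,
               "iteration": r.iteration, "label": r.label}
        row.update(r.flat())
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_records(
    records: Sequence[TrainingRecord], mode: str = "none"
) -> list[TrainingRecord]:
    """Optionally average replications of the same (problem, iteration).

    ``mean_over_replications`` averages numeric features, majority-votes the
    detection flags, and keeps the label (identical across replications by
    construction; a mismatch indicates a chunking bug and raises).
    """
    if mode == "none":
        return list(records)
    if mode != "mean_over_replications":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    groups: dict[tuple[str, int], list[TrainingRecord]] = {}
    for r in records:
        groups.setdefault((r.problem_id, r.iteration), []).append(r)
    out: list[TrainingRecord] = []
    for (pid, iteration), grp in groups.items():
        labels = {r.label for r in grp}
        if len(labels) > 1:
            raise ValueError(
                f"inconsistent labels for problem {pid!r} iteration {iteration}: {labels}"
            )
        features = {
            name: float(np.mean([r.features[name] for r in grp]))
            for name in grp[0].features
        }
        flags = {
            sid: sum(r.flags[sid] for r in grp) * 2 > len(grp)
            for sid in grp[0].flags
        }
        out.append(
            TrainingRecord(
                problem_id=pid, replication=-1, iteration=iteration,
                features=features, flags=flags, label=labels.pop(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# C4.5-style tree induction

def _entropy(pos: float, total: float) -> float:
    if total <= 0 or pos <= 0 or pos >= total:
        return 0.0
    p = pos / total
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def _best_split(values: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best binary threshold on one feature by information gain ratio.

    Returns (gain_ratio, gain, threshold) or None.  ``y`` is a 0/1 vector.
    """
    n = y.size
    order = np.argsort(values, kind="stable")
    vs, ys = values[order], y[order]
    boundaries = np.nonzero(np.diff(vs) > 0)[0]  # split after index i
    if boundaries.size == 0:
        return None
    n_left = boundaries + 1
    n_right = n - n_left
    keep = (n_left >= min_leaf) & (n_right >= min_leaf)
    boundaries, n_left, n_right = boundaries[keep], n_left[keep], n_right[keep]
    if boundaries.size == 0:
        return None
    cum_pos = np.cumsum(ys)
    pos_left = cum_pos[boundaries]
    pos_total = cum_pos[-1]
    pos_right = pos_total - pos_left

    def entropy_vec(pos, tot):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(tot > 0, pos / np.maximum(tot, 1), 0.0)
            h = np.zeros_like(p)
            mask = (p > 0) & (p < 1)
            pm = p[mask]
            h[mask] = -(pm * np.log2(pm) + (1 - pm) * np.log2(1 - pm))
        return h

    parent = _entropy(pos_total, n)
    child = (n_left * entropy_vec(pos_left, n_left) + n_right * entropy_vec(pos_right, n_right)) / n
    gain = parent - child
    frac_l = n_left / n
    split_info = -(frac_l * np.log2(frac_l) + (1 - frac_l) * np.log2(1 - frac_l))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((gain > 1e-12) & (split_info > 0), gain / split_info, -np.inf)
    best = int(np.argmax(ratio))  # smallest qualifying index on ties
    if not np.isfinite(ratio[best]):
        return None
    i = boundaries[best]
    threshold = float((vs[i] + vs[i + 1]) / 2.0)
    return float(ratio[best]), float(gain[best]), threshold


def _leaf_label(y: np.ndarray, over_purity: float) -> str:
    pos = int(y.sum())
    return WARMUP_OVER if y.size and pos >= over_purity * y.size else WARMUP_NOT_OVER


def _grow(X: np.ndarray, y: np.ndarray, names: Sequence[str], min_leaf: int,
          over_purity: float) -> TreeNode:
    if y.size == 0:
        return TreeNode(label=WARMUP_NOT_OVER)
    if np.all(y == y[0]) or y.size < 2 * min_leaf:
        return TreeNode(label=_leaf_label(y, over_purity))
    best = None
    for j, name in enumerate(names):
        cand = _best_split(X[:, j], y, min_leaf)
        if cand is None:
            continue
        # tie-break: higher gain ratio, then feature order, then threshold
        if best is None or cand[0] > best[0][0] + 1e-12:
            best = (cand, j, name)
    if best is None:
        return TreeNode(label=_leaf_label(y, over_purity))
    (ratio, gain, threshold), j, name = best
    mask = X[:, j] <= threshold
    return TreeNode(
        feature=name,
        threshold=threshold,
        left=_grow(X[mask], y[mask], names, min_leaf, over_purity),
        right=_grow(X[~mask], y[~mask], names, min_leaf, over_purity),
    )


def _prune(node: TreeNode, X: np.ndarray, y: np.ndarray,
           names: Sequence[str], z: float, over_purity: float) -> tuple[TreeNode, float]:
    """Return (possibly pruned subtree, pessimistic error count on X)."""

    def upper(err: float, n: float) -> float:
        if n == 0:
            return 0.0
        f = err / n
        denom = 1 + z * z / n
        return (f + z * z / (2 * n)
                + z * math.sqrt(max(f * (1 - f) / n + z * z / (4 * n * n), 0.0))) / denom

    pos = int(y.sum())
    majority = _leaf_label(y, over_purity)
    leaf_err = pos if majority == WARMUP_NOT_OVER else y.size - pos
    leaf_pess = upper(leaf_err, y.size) * y.size if y.size else 0.0
    if node.is_leaf:
        err = int(np.sum(y != (np.full(y.size, node.label == WARMUP_OVER))))
        return node, upper(err, y.size) * y.size if y.size else 0.0
    j = names.index(node.feature)
    mask = X[:, j] <= node.threshold
    left, err_l = _prune(node.left, X[mask], y[mask], names, z, over_purity)
    right, err_r = _prune(node.right, X[~mask], y[~mask], names, z, over_purity)
    subtree_pess = err_l + err_r
    if leaf_pess <= subtree_pess + 0.1:  # C4.5's bias toward the simpler leaf
        return TreeNode(label=majority), leaf_pess
    return TreeNode(feature=node.feature, threshold=node.threshold,
                    left=left, right=right), subtree_pess


def learn_tree(
    records: Sequence[TrainingRecord],
    learner: LearnerParams = LearnerParams(),
    seed: int = 0,
) -> TreeNode:
    """Induce a warm-up classification tree from training records.

    Deterministic given the record order; ``seed`` is reserved for learners
    that subsample.  With a single represented class the result is that
    class as a single leaf.
    """
    if not records:
        raise ValueError("cannot learn from an empty record set")
    names = list(records[0].flat().keys())
    X = np.array([[r.flat()[k] for k in names] for r in records])
    y = np.array([1 if r.label == WARMUP_OVER else 0 for r in records])
    if np.all(y == y[0]):
        return TreeNode(label=WARMUP_OVER if y[0] else WARMUP_NOT_OVER)
    tree = _grow(X, y, names, learner.min_leaf, learner.over_purity)
    if learner.prune:
        z = float(norm.ppf(1 - learner.confidence))
        tree, _ = _prune(tree, X, y, names, z, learner.over_purity)
    return tree


def tree_accuracy(tree: TreeNode, records: Sequence[TrainingRecord]) -> float:
    hits = sum(tree_predict(tree, r.flat()) == r.label for r in records)
    return hits / len(records)


def cross_validate(
    records: Sequence[TrainingRecord],
    k: int,
    learner: LearnerParams = LearnerParams(),
    seed: int = 0,
) -> list[float]:
    """k-fold accuracy with folds partitioned by problem id.

    Grouping by problem prevents leakage between iterations of the same
    series.  Raises if there are fewer distinct problems than folds.
    """
    ids = sorted({r.problem_id for r in records})
    if k > len(ids):
        raise ValueError(f"{k} folds requested but only {len(ids)} distinct problems")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = np.array_split(order, k)
    accuracies: list[float] = []
    for fold in folds:
        held = {ids[i] for i in fold}
        train = [r for r in records if r.problem_id not in held]
        test = [r for r in records if r.problem_id in held]
        tree = learn_tree(train, learner, seed)
        accuracies.append(tree_accuracy(tree, test))
    return accuracies


def premature_detection_rate(records: Sequence[TrainingRecord]) -> float:
    """Fraction of pre-warm-up records where some estimator already fired."""
    pre = [r for r in records if r.label == WARMUP_NOT_OVER]
    if not pre:
        return 0.0
    fired = sum(any(r.flags.values()) for r in pre)
    return fired / len(pre)


# ---------------------------------------------------------------------------
# Deployment

def _feature_ranges(records: Sequence[TrainingRecord]) -> dict[str, list[float]]:
    names = records[0].flat().keys() if records else []
    out = {}
    for name in names:
        vals = [r.flat()[name] for r in records]
        out[name] = [float(min(vals)), float(max(vals))]
    return out


def build_sps(
    tree: TreeNode,
    estimator_ids: Sequence[str],
    metadata: Optional[dict] = None,
    records: Sequence[TrainingRecord] = (),
    params: EstimatorParams = DEFAULT_PARAMS,
) -> tuple[SPSDefinition, dict]:
    """Wrap a learned tree into an SPS definition + JSON-ready descriptor.

    The descriptor records the statistical properties of the training data
    (per-feature value ranges) alongside any caller-provided metadata such
    as the generator grid and master seed.
    """
    valid = set(FEATURE_NAMES) | {f"detected.{sid}" for sid in estimator_ids}

    def check(node: TreeNode) -> None:
        if node.is_leaf:
            return
        if node.feature not in valid:
            raise ValueError(f"tree references unknown feature {node.feature!r}")
        check(node.left)
        check(node.right)

    check(tree)
    meta = dict(metadata or {})
    if records:
        meta["feature_ranges"] = _feature_ranges(records)
    definition = SPSDefinition(
        solvers=list(estimator_ids),
        composer="tree",
        tree=tree,
        params=params,
        metadata=meta,
    )
    return definition, definition_to_descriptor(definition)


def train_sps(
    problems: Sequence[LabeledSeries],
    estimator_ids: Sequence[str] = tuple(DETECTORS),
    config: TrainingConfig = TrainingConfig(),
    params: EstimatorParams = DEFAULT_PARAMS,
    metadata: Optional[dict] = None,
) -> tuple[SPSDefinition, dict, list[float]]:
    """The full training pipeline: collect, aggregate, cross-validate, deploy.

    Returns the SPS definition, its JSON-ready descriptor, and the per-fold
    cross-validated accuracies.  Deterministic given the problems and
    ``config.seed``.
    """
    raw = collect_training_data(problems, estimator_ids, config, params)
    records = aggregate_records(raw, config.aggregate)
    learner = LearnerParams(
        min_leaf=config.min_leaf, confidence=config.confidence, prune=config.prune
    )
    folds = min(config.folds, len({r.problem_id for r in records}))
    accuracies = cross_validate(records, folds, learner, config.seed)
    tree = learn_tree(records, learner, config.seed)
    meta = dict(metadata or {})
    meta.update(
        master_seed=config.seed,
        n_training_series=len(problems),
        premature_detection_rate=premature_detection_rate(raw),
        cv_accuracy_mean=float(np.mean(accuracies)),
        cv_accuracy_sd=float(np.std(accuracies, ddof=1)) if len(accuracies) > 1 else 0.0,
    )
    definition, descriptor = build_sps(tree, estimator_ids, meta, records, params)
    return definition, descriptor, accuracies
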