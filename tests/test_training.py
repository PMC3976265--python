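import json

import numpy as np
import pytest

from spskit import (
    ESTIMATOR_IDS,
    GeneratorSpec,
    LearnerParams,
    ProblemGrid,
    TrainingConfig,
    TrainingRecord,
    aggregate_records,
    build_sps,
    collect_training_data,
    cross_validate,
    generate_problem_set,
    generate_series,
    learn_tree,
    premature_detection_rate,
    train_sps,
    tree_accuracy,
    tree_predict,
)
from spskit.sps import WARMUP_NOT_OVER, WARMUP_OVER


def make_records(values, labels, feature="f", pid_of=None):
    """Synthetic single-feature records for learner tests."""
    out = []
    for i, (v, lab) in enumerate(zip(values, labels)):
        pid = pid_of(i) if pid_of else f"p{i}"
        out.append(TrainingRecord(pid, 0, 1, {feature: float(v)}, {}, lab))
    return out


@pytest.fixture(scope="module")
def small_problems():
    grid = ProblemGrid(bias_fractions=(0.25,), noise_levels=(10.0,),
                       lengths=(500,), replications=2,
                       bias_types=(("constant", "line"), ("quadratic", "oscillating")))
    return generate_problem_set(grid, seed=13)


class TestCollect:
    def test_one_record_per_chunk(self, small_problems):
        records = collect_training_data(small_problems[:1], config=TrainingConfig(chunks=10))
        assert len(records) == 10
        assert [r.iteration for r in records] == list(range(1, 11))

    def test_labels_follow_warmup_length(self, small_problems):
        labeled = small_problems[0]
        records = collect_training_data([labeled], config=TrainingConfig(chunks=10))
        for r in records:
            # warm-up-aligned chunking: first half of the chunks are warm-up
            expected = WARMUP_OVER if r.iteration > 5 else WARMUP_NOT_OVER
            assert r.label == expected

    def test_records_are_reproducible(self, small_problems):
        a = collect_training_data(small_problems[:2])
        b = collect_training_data(small_problems[:2])
        assert [r.features for r in a] == [r.features for r in b]
        assert [r.flags for r in a] == [r.flags for r in b]

    def test_impossible_chunking_is_an_error(self):
        labeled = generate_series(GeneratorSpec(n=5, bias_fraction=0.0, seed=1))
        with pytest.raises(ValueError):
            collect_training_data([labeled], config=TrainingConfig(chunks=10))


class TestAggregate:
    def test_none_is_identity(self):
        recs = make_records([0.1, 0.9], [WARMUP_NOT_OVER, WARMUP_OVER])
        assert aggregate_records(recs, "none") == recs

    def test_mean_over_replications(self):
        recs = [
            TrainingRecord("p", 0, 1, {"f": 0.2}, {"mser": True}, WARMUP_OVER),
            TrainingRecord("p", 1, 1, {"f": 0.4}, {"mser": True}, WARMUP_OVER),
            TrainingRecord("p", 2, 1, {"f": 0.6}, {"mser": False}, WARMUP_OVER),
        ]
        (agg,) = aggregate_records(recs, "mean_over_replications")
        assert agg.features["f"] == pytest.approx(0.4)
        assert agg.flags["mser"] is True  # 2-of-3 majority
        assert agg.label == WARMUP_OVER

    def test_inconsistent_labels_raise(self):
        recs = [
            TrainingRecord("p", 0, 1, {"f": 0.2}, {}, WARMUP_OVER),
            TrainingRecord("p", 1, 1, {"f": 0.4}, {}, WARMUP_NOT_OVER),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            aggregate_records(recs, "mean_over_replications")


class TestLearnTree:
    def test_single_class_gives_single_leaf(self):
        recs = make_records([0.1, 0.2, 0.3], [WARMUP_OVER] * 3)
        tree = learn_tree(recs)
        assert tree.is_leaf and tree.label == WARMUP_OVER

    def test_recovers_planted_threshold(self, rng):
        values = rng.uniform(0, 1, 100)
        labels = [WARMUP_OVER if v >= 0.5 else WARMUP_NOT_OVER for v in values]
        recs = make_records(values, labels)
        tree = learn_tree(recs, LearnerParams(min_leaf=1))
        assert tree_accuracy(tree, recs) == 1.0
        assert not tree.is_leaf
        lo = values[values < 0.5].max()
        hi = values[values >= 0.5].min()
        assert lo <= tree.threshold <= hi  # within the data margin

    def test_threshold_matches_exhaustive_search_on_margin(self):
        # equally spaced values, clean split: the midpoint is forced
        values = np.linspace(0, 1, 100)
        labels = [WARMUP_NOT_OVER if v < 0.5 else WARMUP_OVER for v in values]
        tree = learn_tree(make_records(values, labels), LearnerParams(min_leaf=1))
        assert 0.49 < tree.threshold < 0.51

    def test_xor_needs_depth_two(self, rng):
        xs = rng.uniform(0, 1, (200, 2))
        out = []
        for i, (a, b) in enumerate(xs):
            label = WARMUP_OVER if (a > 0.5) != (b > 0.5) else WARMUP_NOT_OVER
            out.append(TrainingRecord(f"p{i}", 0, 1, {"a": a, "b": b}, {}, label))
        tree = learn_tree(out, LearnerParams(min_leaf=1, prune=False))
        assert tree_accuracy(tree, out) == 1.0
        assert not tree.is_leaf and not (tree.left.is_leaf and tree.right.is_leaf)

    def test_empty_record_set_is_an_error(self):
        with pytest.raises(ValueError):
            learn_tree([])

    def test_matches_reference_tree_learner_on_noisy_data(self, rng):
        # independent cross-check: on the same records, the native gain-ratio
        # tree should generalize comparably to a reference CART learner
        from sklearn.tree import DecisionTreeClassifier

        values = rng.uniform(0, 1, (300, 2))
        noise = rng.uniform(size=300) < 0.1
        raw = (values[:, 0] > 0.6) | (values[:, 1] > 0.7)
        labels = np.where(raw ^ noise, WARMUP_OVER, WARMUP_NOT_OVER)
        recs = [TrainingRecord(f"p{i}", 0, 1,
                               {"a": float(a), "b": float(b)}, {}, lab)
                for i, ((a, b), lab) in enumerate(zip(values, labels))]
        mine = learn_tree(recs, LearnerParams(min_leaf=10, over_purity=0.5))
        acc_mine = tree_accuracy(mine, recs)
        ref = DecisionTreeClassifier(min_samples_leaf=10, random_state=0)
        ref.fit(values, labels == WARMUP_OVER)
        acc_ref = ref.score(values, labels == WARMUP_OVER)
        assert acc_mine >= acc_ref - 0.05

    def test_deterministic_given_records(self, rng):
        values = rng.uniform(0, 1, 60)
        labels = [WARMUP_OVER if v > 0.3 else WARMUP_NOT_OVER for v in values]
        recs = make_records(values, labels)
        t1, t2 = learn_tree(recs), learn_tree(recs)
        assert t1.to_dict() == t2.to_dict()


class TestCrossValidate:
    def test_separable_data_with_margin_is_perfect(self, rng):
        # a clear margin around the class boundary, so no held-out point can
        # fall inside a fold's training margin
        values = np.concatenate([rng.uniform(0, 0.45, 50), rng.uniform(0.55, 1, 50)])
        labels = [WARMUP_OVER if v >= 0.5 else WARMUP_NOT_OVER for v in values]
        accs = cross_validate(make_records(values, labels), 5, LearnerParams(min_leaf=1))
        assert accs == [1.0] * 5

    def test_returns_exactly_k_values(self, rng):
        values = rng.uniform(0, 1, 30)
        labels = [WARMUP_OVER if v > 0.5 else WARMUP_NOT_OVER for v in values]
        assert len(cross_validate(make_records(values, labels), 3)) == 3

    def test_shuffled_labels_hover_at_chance(self):
        gen = np.random.default_rng(77)
        values = gen.uniform(0, 1, 500)
        labels = list(np.where(gen.uniform(size=500) < 0.5, WARMUP_OVER, WARMUP_NOT_OVER))
        accs = cross_validate(make_records(values, labels), 5, LearnerParams(min_leaf=5))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_more_folds_than_problems_is_an_error(self):
        recs = make_records([0.1, 0.9], [WARMUP_NOT_OVER, WARMUP_OVER],
                            pid_of=lambda i: "shared")
        with pytest.raises(ValueError):
            cross_validate(recs, 2)


class TestBuildAndDeploy:
    def test_descriptor_lists_all_ten_estimators(self, rng):
        values = rng.uniform(0, 1, 40)
        labels = [WARMUP_OVER if v > 0.5 else WARMUP_NOT_OVER for v in values]
        recs = make_records(values, labels, feature="frac_above")
        tree = learn_tree(recs, LearnerParams(min_leaf=1))
        definition, descriptor = build_sps(tree, list(ESTIMATOR_IDS),
                                           metadata={"grid": "unit", "seed": 1},
                                           records=recs)
        assert descriptor["solvers"] == list(ESTIMATOR_IDS)
        assert descriptor["metadata"]["grid"] == "unit"
        assert "feature_ranges" in descriptor["metadata"]

    def test_unknown_tree_feature_is_an_error(self):
        from spskit import TreeNode

        bad = TreeNode(feature="not_a_feature", threshold=0.5,
                       left=TreeNode(label=WARMUP_NOT_OVER),
                       right=TreeNode(label=WARMUP_OVER))
        with pytest.raises(ValueError, match="not_a_feature"):
            build_sps(bad, list(ESTIMATOR_IDS))

    def test_round_trip_predictions(self, rng):
        from spskit.sps import definition_from_descriptor

        values = rng.uniform(0, 1, 40)
        labels = [WARMUP_OVER if v > 0.5 else WARMUP_NOT_OVER for v in values]
        recs = make_records(values, labels, feature="frac_above")
        tree = learn_tree(recs, LearnerParams(min_leaf=1))
        definition, descriptor = build_sps(tree, list(ESTIMATOR_IDS), records=recs)
        loaded = definition_from_descriptor(json.loads(json.dumps(descriptor)))
        for _ in range(100):
            record = {"frac_above": float(rng.uniform())}
            assert tree_predict(loaded.tree, record) == tree_predict(tree, record)

    def test_end_to_end_determinism(self, small_problems):
        cfg = TrainingConfig(seed=5)
        _, d1, _ = train_sps(small_problems, config=cfg)
        _, d2, _ = train_sps(small_problems, config=cfg)
        assert json.dumps(d1, sort_keys=True) == json.dumps(d2, sort_keys=True)

    def test_premature_rate_is_a_fraction(self, small_problems):
        records = collect_training_data(small_problems)
        assert 0.0 <= premature_detection_rate(records) <= 1.0
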