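import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trialmine.errors import EvaluationError, ValidationError
from trialmine.evaluate import (
    arm_assignment_accuracy,
    human_benchmark,
    krippendorff_alpha,
    make_cv_folds,
    match_annotations,
    micro_f1,
    precision_recall_f1,
    score_counts,
    summarize,
)
from trialmine.schema import AnnotatedStudy, Annotation
from trialmine.simulate import corrupt_annotations, default_signal_config, generate_corpus


def _study(doc_id, items):
    """items: list of (entity_id, value)."""
    return AnnotatedStudy(
        doc_id=doc_id,
        annotations=[
            Annotation(doc_id=doc_id, entity_id=eid, value=value)
            for eid, value in items
        ],
    )


class TestMatchAnnotations:
    def test_identical_sets(self, schema):
        gold = [_study("d1", [("mean_age", 44.5), ("bct_reward", None)])]
        counts = match_annotations(gold, gold, schema)
        tp, fp, fn = counts.totals()
        assert (fp, fn) == (0, 0) and tp == 2

    def test_value_match_is_tp(self, schema):
        gold = [_study("d1", [("mean_age", 44.5)])]
        pred = [_study("d1", [("mean_age", 44.5)])]
        assert match_annotations(gold, pred, schema).totals() == (1, 0, 0)

    def test_value_mismatch_is_fp_and_fn(self, schema):
        gold = [_study("d1", [("mean_age", 44.5)])]
        pred = [_study("d1", [("mean_age", 44.6)])]
        assert match_annotations(gold, pred, schema).totals() == (0, 1, 1)

    def test_partial_match_counts(self, schema):
        # brute-force bipartite count: 2 gold, 1 matching prediction
        gold = [_study("d1", [("bct_reward", None), ("bct_reward", None)])]
        pred = [_study("d1", [("bct_reward", None)])]
        counts = match_annotations(gold, pred, schema)
        assert counts.per_entity["bct_reward"] == (1, 0, 1)

    def test_unknown_entity_rejected(self, schema):
        gold = [_study("d1", [("no_such_entity", None)])]
        with pytest.raises(ValidationError):
            match_annotations(gold, gold, schema)

    def test_strict_mode_requires_span_equality(self, schema):
        text = "aged 44.5 years overall"
        gold = AnnotatedStudy(
            doc_id="d1",
            text=text,
            annotations=[
                Annotation("d1", "mean_age", span=(5, 15),
                           raw_text="44.5 years", value=44.5)
            ],
        )
        pred_wrong_span = AnnotatedStudy(
            doc_id="d1",
            text=text,
            annotations=[
                Annotation("d1", "mean_age", span=(5, 9),
                           raw_text="44.5", value=44.5)
            ],
        )
        assert match_annotations([gold], [pred_wrong_span], schema,
                                 "entity").totals() == (1, 0, 0)
        assert match_annotations([gold], [pred_wrong_span], schema,
                                 "strict").totals() == (0, 1, 1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 5), st.integers(0, 5), st.integers(0, 5))
    def test_instance_conservation(self, n_match, n_gold_only, n_pred_only):
        from trialmine.schema import EntityKind, EntitySpec

        schema = [
            EntitySpec("e_match", "", EntityKind.value, value_unit="u"),
            EntitySpec("e_gold", "", EntityKind.value, value_unit="u"),
            EntitySpec("e_pred", "", EntityKind.value, value_unit="u"),
        ]
        gold = [_study("d1", [("e_match", float(i)) for i in range(n_match)]
                       + [("e_gold", float(i)) for i in range(n_gold_only)])]
        pred = [_study("d1", [("e_match", float(i)) for i in range(n_match)]
                       + [("e_pred", float(i)) for i in range(n_pred_only)])]
        tp, fp, fn = match_annotations(gold, pred, schema).totals()
        assert tp + fp == n_match + n_pred_only
        assert tp + fn == n_match + n_gold_only


class TestPrecisionRecallF1:
    def test_perfect(self):
        score = precision_recall_f1(2, 0, 0)
        assert (score.precision, score.recall, score.f1) == (1.0, 1.0, 1.0)

    def test_zero_tp_gives_zero_f1(self):
        assert precision_recall_f1(0, 3, 5).f1 == 0.0

    def test_formula_example(self):
        score = precision_recall_f1(3, 2, 7)
        assert score.precision == pytest.approx(0.6)
        assert score.recall == pytest.approx(0.3)
        assert score.f1 == pytest.approx(0.4)  # 2*0.6*0.3/0.9

    def test_all_zero_counts(self):
        score = precision_recall_f1(0, 0, 0)
        assert (score.precision, score.recall, score.f1) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_bounds_and_identities(self, tp, fp, fn):
        score = precision_recall_f1(tp, fp, fn)
        assert 0.0 <= score.precision <= 1.0
        assert 0.0 <= score.recall <= 1.0
        assert 0.0 <= score.f1 <= max(score.precision, score.recall) + 1e-12
        if tp == 0:
            assert score.f1 == 0.0
        if fp == fn:
            assert score.f1 == pytest.approx(score.precision)


class TestSummarize:
    def _scores(self, f1s):
        return {
            f"e{i}": precision_recall_f1(1, 0, 0) for i, _ in enumerate(f1s)
        } | {
            f"x{i}": type(precision_recall_f1(1, 0, 0))(f, f, f)
            for i, f in enumerate(f1s)
        }

    def test_summary_statistics(self):
        from trialmine.evaluate import EntityScore

        scores = {
            "a": EntityScore(0.2, 0.2, 0.2),
            "b": EntityScore(0.4, 0.4, 0.4),
            "c": EntityScore(0.6, 0.6, 0.6),
        }
        report = summarize(scores)
        assert report.summary == pytest.approx(
            {"mean": 0.4, "median": 0.4, "maximum": 0.6, "minimum": 0.2}
        )

    def test_single_entity(self):
        from trialmine.evaluate import EntityScore

        report = summarize({"a": EntityScore(0.7, 0.7, 0.7)})
        assert set(report.summary.values()) == {0.7}

    def test_benchmark_column(self):
        from trialmine.evaluate import EntityScore

        scores = {"a": EntityScore(1, 1, 1)}
        bench = {"a": EntityScore(0.5, 0.5, 0.5)}
        report = summarize(scores, benchmark=bench)
        assert report.benchmark_summary["mean"] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            summarize({})


class TestHumanBenchmark:
    def test_identical_annotators(self, schema):
        a = [_study("d1", [("mean_age", 44.5), ("bct_reward", None)])]
        report = human_benchmark(a, a, schema)
        assert report.summary["mean"] == 1.0

    def test_empty_second_annotator(self, schema):
        a = [_study("d1", [("mean_age", 44.5)])]
        b = [_study("d1", [])]
        report = human_benchmark(a, b, schema)
        assert report.summary["mean"] == 0.0

    def test_swap_leaves_f1_unchanged(self, schema):
        a = [_study("d1", [("mean_age", 44.5), ("pct_female", 60.0)])]
        b = [_study("d1", [("mean_age", 44.5), ("pct_female", 59.0),
                           ("bct_reward", None)])]
        ab = human_benchmark(a, b, schema)
        ba = human_benchmark(b, a, schema)
        for eid in ab.per_entity:
            assert ab.per_entity[eid].f1 == pytest.approx(ba.per_entity[eid].f1)
            assert ab.per_entity[eid].precision == pytest.approx(
                ba.per_entity[eid].recall
            )

    def test_disjoint_documents_rejected(self, schema):
        a = [_study("d1", [("mean_age", 44.5)])]
        b = [_study("d2", [("mean_age", 44.5)])]
        with pytest.raises(EvaluationError):
            human_benchmark(a, b, schema)


def alpha_oracle(codes_a, codes_b):
    """Brute-force nominal alpha via explicit pooled-pair enumeration."""
    n = len(codes_a)
    pooled = list(codes_a) + list(codes_b)
    N = len(pooled)
    # observed: ordered within-unit pairs
    d_o = sum(2 * (a != b) for a, b in zip(codes_a, codes_b)) / N
    # expected: ordered pairs across the pooled values
    disagreements = 0
    for i in range(N):
        for j in range(N):
            if i != j and pooled[i] != pooled[j]:
                disagreements += 1
    d_e = disagreements / (N * (N - 1))
    if d_e == 0:
        return 1.0
    return 1.0 - d_o / d_e


class TestKrippendorffAlpha:
    def test_identical_coding(self):
        report = krippendorff_alpha([1, 0, 1, 2], [1, 0, 1, 2])
        assert report.alpha == 1.0

    def test_small_example_matches_oracle(self):
        a, b = [1, 1, 0, 0], [1, 0, 0, 0]
        report = krippendorff_alpha(a, b)
        assert report.alpha == pytest.approx(alpha_oracle(a, b))

    def test_independent_coding_near_zero(self):
        rng = np.random.default_rng(123)
        a = rng.integers(0, 2, size=10_000).tolist()
        b = rng.integers(0, 2, size=10_000).tolist()
        report = krippendorff_alpha(a, b)
        assert abs(report.alpha) < 0.05

    def test_degenerate_single_category_warns(self):
        with pytest.warns(UserWarning):
            report = krippendorff_alpha([1, 1, 1], [1, 1, 1])
        assert report.alpha == 1.0 and report.degenerate

    def test_monotone_under_single_item_corruption(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, size=200).tolist()
        b = list(a)
        previous = krippendorff_alpha(a, b).alpha
        for i in range(0, 40, 5):
            b[i] = (b[i] + 1) % 3
            current = krippendorff_alpha(a, b).alpha
            assert current < previous + 1e-12
            previous = current

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(EvaluationError):
            krippendorff_alpha([1, 2], [1])


class TestMakeCVFolds:
    def test_10_studies_5_folds(self):
        ids = [f"s{i}" for i in range(10)]
        folds = make_cv_folds(ids, 5, seed=0)
        assert [len(f) for f in folds.folds] == [2] * 5
        flat = [i for f in folds.folds for i in f]
        assert sorted(flat) == sorted(ids)

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(13)]
        assert make_cv_folds(ids, 5, 3).folds == make_cv_folds(ids, 5, 3).folds

    def test_sizes_differ_by_at_most_one(self):
        folds = make_cv_folds([f"s{i}" for i in range(13)], 5, 0)
        sizes = [len(f) for f in folds.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_k1_degenerate_warns(self):
        with pytest.warns(UserWarning):
            folds = make_cv_folds(["a", "b"], 1, 0)
        assert len(folds.folds) == 1

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(EvaluationError):
            make_cv_folds(["a"], 2, 0)


class TestCorruptionDegradesScores:
    def test_f1_degrades_monotonically_with_drop_rate(self, schema):
        corpus = generate_corpus(default_signal_config(seed=21, n_docs=15))
        gold = [g.study for g in corpus]
        previous = 1.1
        for rate in (0.0, 0.3, 0.6, 1.0):
            degraded = corrupt_annotations(gold, drop_rate=rate, seed=5)
            score = micro_f1(match_annotations(gold, degraded, schema))
            assert score <= previous + 1e-9
            previous = score
        assert previous == 0.0  # drop rate 1 -> recall 0


class TestArmAssignmentAccuracy:
    def test_perfect_assignments(self, schema):
        corpus = generate_corpus(default_signal_config(seed=22, n_docs=5))
        gold = [g.study for g in corpus]
        assert arm_assignment_accuracy(gold, gold) == 1.0
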