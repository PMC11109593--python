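import dataclasses
import itertools

import networkx as nx
import numpy as np
import pytest

from trialmine.errors import TrainingError
from trialmine.evaluate import make_cv_folds
from trialmine.predict import (
    GraphEmbeddingConfig,
    PredictionModelConfig,
    Standardizer,
    build_cooccurrence_graph,
    build_feature_vectors,
    design_matrix,
    evaluate_prediction,
    feature_entities,
    fit_grand_mean,
    fit_linear_baseline,
    fit_recurrent_model,
    learn_graph_embeddings,
    rmse,
)
from trialmine.schema import (
    AnnotatedStudy,
    Annotation,
    Arm,
    OutcomeRecord,
)
from trialmine.simulate import (
    default_signal_config,
    generate_corpus,
    strong_signal_config,
)


def _two_arm_study(doc_id="d1", outcomes=(20.0, 30.0)):
    arms = [Arm(arm_id=f"arm_{i+1}", label=f"a{i+1}") for i in range(2)]
    return AnnotatedStudy(
        doc_id=doc_id,
        arms=arms,
        annotations=[
            Annotation(doc_id, "mean_age", value=44.5),  # WHOLE_STUDY
            Annotation(doc_id, "bct_reward", arm_ref="arm_1"),
            Annotation(doc_id, "sessions_count", value=8.0, arm_ref="arm_2"),
        ],
        outcomes=[
            OutcomeRecord(f"arm_{i+1}", "outcome_abstinence_12m", v)
            for i, v in enumerate(outcomes)
        ],
    )


class TestBuildFeatureVectors:
    def test_whole_study_value_propagates_to_all_arms(self, schema):
        vectors = build_feature_vectors([_two_arm_study()], schema)
        assert len(vectors) == 2
        _, numeric_ids = feature_entities(schema)
        age_idx = numeric_ids.index("mean_age")
        assert all(v.numeric[age_idx] == 44.5 for v in vectors)

    def test_arm_scoped_annotation_stays_on_its_arm(self, schema):
        vectors = build_feature_vectors([_two_arm_study()], schema)
        presence_ids, _ = feature_entities(schema)
        reward_idx = presence_ids.index("bct_reward")
        by_arm = {v.arm_id: v for v in vectors}
        assert by_arm["arm_1"].presence[reward_idx] == 1.0
        assert by_arm["arm_2"].presence[reward_idx] == 0.0

    def test_arm_without_outcome_gets_no_vector(self, schema):
        study = _two_arm_study()
        study.outcomes = study.outcomes[:1]
        vectors = build_feature_vectors([study], schema)
        assert [v.arm_id for v in vectors] == ["arm_1"]

    def test_study_without_outcome_skipped_with_warning(self, schema):
        study = _two_arm_study()
        study.outcomes = []
        with pytest.warns(UserWarning):
            assert build_feature_vectors([study], schema) == []

    def test_design_matrix_width_is_presence_plus_twice_value(self, schema):
        vectors = build_feature_vectors([_two_arm_study()], schema)
        X, _ = design_matrix(vectors, Standardizer.fit(vectors))
        presence_ids, numeric_ids = feature_entities(schema)
        assert X.shape[1] == len(presence_ids) + 2 * len(numeric_ids)

    def test_longest_followup_outcome_wins(self, schema):
        study = _two_arm_study()
        study.outcomes.append(
            OutcomeRecord("arm_1", "outcome_abstinence_6m", 99.0)
        )
        vectors = build_feature_vectors([study], schema)
        by_arm = {v.arm_id: v for v in vectors}
        assert by_arm["arm_1"].outcome == 20.0  # 12m entity outranks 6m


class TestCooccurrenceGraph:
    def test_counting_example(self):
        studies = [
            AnnotatedStudy("d1", annotations=[
                Annotation("d1", "A"), Annotation("d1", "B")]),
            AnnotatedStudy("d2", annotations=[
                Annotation("d2", "A"), Annotation("d2", "B"),
                Annotation("d2", "C")]),
        ]
        g = build_cooccurrence_graph(studies)
        assert g["A"]["B"]["weight"] == 2
        assert g["A"]["C"]["weight"] == 1
        assert g["B"]["C"]["weight"] == 1

    def test_single_entity_document_contributes_no_edges(self):
        g = build_cooccurrence_graph(
            [AnnotatedStudy("d1", annotations=[Annotation("d1", "A")])]
        )
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_empty_corpus(self):
        g = build_cooccurrence_graph([])
        assert g.number_of_nodes() == 0

    def test_no_self_loops_and_symmetry(self, small_corpus):
        g = build_cooccurrence_graph([x.study for x in small_corpus])
        assert not any(a == b for a, b in g.edges)
        for a, b in g.edges:
            assert g[a][b]["weight"] >= 1


class TestGraphEmbeddings:
    def test_vector_length_matches_dimensions(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(5)})
        nx.set_edge_attributes(g, 1, "weight")
        vectors = learn_graph_embeddings(g, GraphEmbeddingConfig(dimensions=16))
        assert all(len(v) == 16 for v in vectors.values())

    def test_deterministic_given_seed(self):
        g = nx.relabel_nodes(nx.cycle_graph(6), lambda i: f"n{i}")
        nx.set_edge_attributes(g, 1, "weight")
        config = GraphEmbeddingConfig(dimensions=8, seed=4)
        a = learn_graph_embeddings(g, config)
        b = learn_graph_embeddings(g, config)
        for node in a:
            assert np.array_equal(a[node], b[node])

    def test_disjoint_cliques_separate(self):
        g = nx.Graph()
        for base in (0, 5):
            for i, j in itertools.combinations(range(5), 2):
                g.add_edge(f"n{base+i}", f"n{base+j}", weight=1)
        vectors = learn_graph_embeddings(
            g, GraphEmbeddingConfig(dimensions=8, seed=3)
        )

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        within, between = [], []
        for a, b in itertools.combinations(sorted(g.nodes), 2):
            same = (int(a[1:]) < 5) == (int(b[1:]) < 5)
            (within if same else between).append(cos(vectors[a], vectors[b]))
        assert np.mean(within) > np.mean(between)

    def test_empty_graph_rejected(self):
        with pytest.raises(TrainingError):
            learn_graph_embeddings(nx.Graph(), GraphEmbeddingConfig())


class TestGrandMean:
    def test_predicts_training_mean(self):
        model = fit_grand_mean(np.array([10.0, 20.0, 30.0]))
        assert np.all(model.predict(np.zeros((4, 2))) == 20.0)

    def test_single_value(self):
        assert fit_grand_mean(np.array([7.0])).predict(np.zeros((1, 1)))[0] == 7.0

    def test_training_rmse_equals_population_sd(self):
        rng = np.random.default_rng(0)
        y = rng.normal(25, 9, size=200)
        model = fit_grand_mean(y)
        assert rmse(model.predict(np.zeros((len(y), 1))), y) == pytest.approx(
            float(np.std(y))
        )

    def test_empty_rejected(self):
        with pytest.raises(TrainingError):
            fit_grand_mean(np.array([]))


class TestLinearBaseline:
    def test_exact_fit(self):
        x = np.linspace(0, 10, 20).reshape(-1, 1)
        y = 2 + 3 * x[:, 0]
        model = fit_linear_baseline(x, y)
        assert model.intercept == pytest.approx(2.0)
        assert model.coef[0] == pytest.approx(3.0)
        assert rmse(model.predict(x), y) == pytest.approx(0.0, abs=1e-9)

    def test_constant_outcome(self):
        x = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.full(10, 5.0)
        model = fit_linear_baseline(x, y)
        assert model.coef[0] == pytest.approx(0.0, abs=1e-9)
        assert model.intercept == pytest.approx(5.0)

    def test_collinear_column_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2))
        y = 1 + x @ np.array([2.0, -1.0]) + rng.normal(0, 0.1, 30)
        base = fit_linear_baseline(x, y).predict(x)
        doubled = np.hstack([x, x[:, :1]])  # duplicate first column
        dup = fit_linear_baseline(doubled, y).predict(doubled)
        assert np.allclose(base, dup, atol=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(TrainingError):
            fit_linear_baseline(np.zeros((1, 2)), np.zeros(1))


class TestRecurrentModel:
    def _vectors_and_studies(self, config, n_docs):
        corpus = generate_corpus(
            dataclasses.replace(config, n_docs=n_docs)
        )
        studies = [g.study for g in corpus]
        return studies

    def test_zero_variance_outcomes_predict_constant(self, schema):
        studies = []
        for i in range(6):
            s = _two_arm_study(doc_id=f"d{i}", outcomes=(42.0, 42.0))
            studies.append(s)
        vectors = build_feature_vectors(studies, schema)
        config = PredictionModelConfig(
            family="entities_only", epochs=10,
            graph=GraphEmbeddingConfig(dimensions=4, walks_per_node=2,
                                       walk_length=5),
        )
        model = fit_recurrent_model(vectors, config, studies, schema)
        preds = model.predict(vectors)
        assert np.all(np.abs(preds - 42.0) <= 0.5)

    def test_noise_free_linear_corpus_low_training_rmse(self, schema):
        config = dataclasses.replace(
            strong_signal_config(seed=31), noise_sd=0.0, n_docs=25
        )
        studies = [g.study for g in generate_corpus(config)]
        vectors = build_feature_vectors(studies, schema)
        model_config = PredictionModelConfig(
            family="entities_only",
            layer_sizes=(24,),
            epochs=1500,
            learning_rate=0.01,
            seed=2,
            graph=GraphEmbeddingConfig(dimensions=8, seed=2),
        )
        model = fit_recurrent_model(vectors, model_config, studies, schema)
        preds = model.predict(vectors)
        gold = np.array([v.outcome for v in vectors])
        assert rmse(preds, gold) < 1.0

    def test_deterministic_given_seed(self, schema):
        studies = [
            _two_arm_study(doc_id=f"d{i}", outcomes=(20.0 + i, 30.0 - i))
            for i in range(6)
        ]
        vectors = build_feature_vectors(studies, schema)
        config = PredictionModelConfig(
            family="entities_only", epochs=20, seed=5,
            graph=GraphEmbeddingConfig(dimensions=4, walks_per_node=2,
                                       walk_length=5, seed=5),
        )
        a = fit_recurrent_model(vectors, config, studies, schema).predict(vectors)
        b = fit_recurrent_model(vectors, config, studies, schema).predict(vectors)
        assert np.array_equal(a, b)


class TestEvaluatePrediction:
    def test_rmse_formula_examples(self):
        assert rmse(np.array([10.0, 10.0]), np.array([10.0, 10.0])) == 0.0
        assert rmse(np.array([12.0, 8.0]), np.array([10.0, 10.0])) == pytest.approx(2.0)

    def test_report_rows_ordered_and_complete(self, schema):
        corpus = generate_corpus(default_signal_config(seed=32, n_docs=15))
        studies = [g.study for g in corpus]
        folds = make_cv_folds([s.doc_id for s in studies], 3, seed=0)
        report = evaluate_prediction(
            studies, folds, schema,
            model_families=("grand_mean", "linear"), seed=0,
        )
        assert list(report.mean_rmse) == ["grand_mean", "linear"]
        assert all(v >= 0 for v in report.mean_rmse.values())
        assert all(len(v) == 3 for v in report.fold_rmse.values())

    def test_strong_signal_linear_beats_grand_mean(self, schema):
        corpus = generate_corpus(strong_signal_config(seed=33, n_docs=60))
        studies = [g.study for g in corpus]
        folds = make_cv_folds([s.doc_id for s in studies], 5, seed=1)
        report = evaluate_prediction(
            studies, folds, schema,
            model_families=("grand_mean", "linear"), seed=1,
        )
        assert report.mean_rmse["linear"] < report.mean_rmse["grand_mean"]

    def test_gradient_against_numerical_check(self):
        """Backprop through the LSTM matches a finite-difference gradient."""
        from trialmine._recurrent import LSTMRegressor

        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3, 2))
        y = rng.normal(size=4) * 10 + 30
        model = LSTMRegressor(layer_sizes=(3,), epochs=1, learning_rate=0.0,
                              seed=0)
        model.fit(X, y)  # builds layers; lr=0 leaves weights at init
        layer = model._layers[0]
        yz = (y - model._y_mean) / model._y_std

        def loss():
            pred, _, _ = model._forward(X)
            return float(np.mean((pred - yz) ** 2))

        hs, cache = layer.forward(X)
        pred, last, caches = model._forward(X)
        d_pred = 2.0 * (pred - yz) / len(X)
        d_hs = np.zeros_like(hs)
        d_hs[:, -1] = np.outer(d_pred, model._w_out)
        _, grads = layer.backward(d_hs, cache)

        eps = 1e-6
        for param, grad in zip(layer.params(), grads):
            idx = (0,) * param.ndim
            orig = param[idx]
            param[idx] = orig + eps
            up = loss()
            param[idx] = orig - eps
            down = loss()
            param[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(grad[idx], rel=1e-4, abs=1e-7)
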