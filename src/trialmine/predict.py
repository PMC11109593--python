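"""Outcome prediction: per-arm feature vectors, annotation co-occurrence
graph, biased-random-walk graph embeddings, baselines and a stacked
recurrent regressor, evaluated by cross-validated RMSE.

Model families (report row order is fixed):

``grand_mean``
    always predicts the mean training outcome — no covariate information;
``linear``
    additive least-squares regression on all features jointly;
``entities_only`` / ``entities_plus_text``
    a stacked-LSTM regressor consuming the schema-ordered sequence of
    per-entity graph embeddings scaled by presence/value, optionally
    concatenated with mean-pooled context-text embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._recurrent import LSTMRegressor
from .embeddings import mean_pool, train_skipgram
from .errors import TrainingError, ValidationError
from .schema import (
    WHOLE_STUDY,
    AnnotatedStudy,
    EntityKind,
    EntitySpec,
)
from .evaluate import CVFolds
from .tagging import tokenize

MODEL_ROW_ORDER = ("grand_mean", "linear", "entities_only", "entities_plus_text")

#: Outcome entities, ordered by follow-up length (longest last wins).
DEFAULT_OUTCOME_ENTITIES = ("outcome_abstinence_6m", "outcome_abstinence_12m")


@dataclass
class FeatureVector:
    study_id: str
    arm_id: str
    presence: np.ndarray  # one flag per presence-absence entity, schema order
    numeric: np.ndarray  # raw values per value entity; NaN where missing
    context_tokens: list[str]
    outcome: float


@dataclass
class GraphEmbeddingConfig:
    dimensions: int = 16
    walks_per_node: int = 10
    walk_length: int = 20
    p: float = 1.0  # return bias
    q: float = 1.0  # in-out bias
    window: int = 3
    epochs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dimensions", "walks_per_node", "walk_length", "window",
                     "epochs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.p <= 0 or self.q <= 0:
            raise ValidationError("p and q must be positive")


@dataclass
class PredictionModelConfig:
    family: str = "linear"
    layer_sizes: tuple[int, ...] = (16,)
    feature_mode: str = "entities_only"
    seed: int = 0
    epochs: int = 200
    learning_rate: float = 0.02
    text_dim: int = 8
    graph: GraphEmbeddingConfig = field(default_factory=GraphEmbeddingConfig)

    def __post_init__(self) -> None:
        if self.family not in MODEL_ROW_ORDER:
            raise ValidationError(f"unknown model family {self.family!r}")
        if not self.layer_sizes:
            raise ValidationError("recurrent stack needs >= 1 layer")


@dataclass
class RMSEReport:
    """Per-model RMSE averaged over folds, rows in MODEL_ROW_ORDER."""

    mean_rmse: dict[str, float]
    fold_rmse: dict[str, list[float]]
    seed: int
    k: int


def feature_entities(
    schema: list[EntitySpec],
    outcome_entity_ids: tuple[str, ...] = DEFAULT_OUTCOME_ENTITIES,
) -> tuple[list[str], list[str]]:
    """Schema-ordered (presence entity ids, value entity ids) used as features.

    Outcome entities are excluded from the feature set; complex components
    are not vectorized (features are one flag per presence entity and one
    number per value entity).
    """
    presence = [
        s.entity_id for s in schema if s.kind is EntityKind.presence_absence
    ]
    numeric = [
        s.entity_id
        for s in schema
        if s.kind is EntityKind.value and s.entity_id not in outcome_entity_ids
    ]
    return presence, numeric


def build_feature_vectors(
    studies: list[AnnotatedStudy],
    schema: list[EntitySpec],
    outcome_entity_ids: tuple[str, ...] = DEFAULT_OUTCOME_ENTITIES,
) -> list[FeatureVector]:
    """One raw (unstandardized) vector per arm that has an outcome record.

    Whole-study annotations propagate to every arm; missing numeric values
    stay NaN (they become a missingness flag plus 0 after fold-wise
    standardization).  Studies without any outcome are skipped with a
    warning.  When several outcome entities are recorded for an arm, the
    one latest in ``outcome_entity_ids`` (longest follow-up) wins.
    """
    presence_ids, numeric_ids = feature_entities(schema, outcome_entity_ids)
    p_index = {eid: i for i, eid in enumerate(presence_ids)}
    n_index = {eid: i for i, eid in enumerate(numeric_ids)}
    priority = {eid: i for i, eid in enumerate(outcome_entity_ids)}

    vectors: list[FeatureVector] = []
    for study in studies:
        outcomes: dict[str, tuple[int, float]] = {}
        for rec in study.outcomes:
            rank = priority.get(rec.entity_id)
            if rank is None:
                continue
            prev = outcomes.get(rec.arm_id)
            if prev is None or rank > prev[0]:
                outcomes[rec.arm_id] = (rank, rec.value)
        if not outcomes:
            warnings.warn(f"study {study.doc_id} has no outcome; skipped")
            continue
        arm_ids = [a.arm_id for a in study.arms] or list(outcomes)
        for arm_id in arm_ids:
            if arm_id not in outcomes:
                continue
            presence = np.zeros(len(presence_ids))
            numeric = np.full(len(numeric_ids), np.nan)
            tokens: list[str] = []
            for ann in study.annotations:
                if ann.arm_ref not in (arm_id, WHOLE_STUDY):
                    continue
                if ann.entity_id in p_index:
                    presence[p_index[ann.entity_id]] = 1.0
                elif ann.entity_id in n_index and ann.value is not None:
                    idx = n_index[ann.entity_id]
                    if np.isnan(numeric[idx]):
                        numeric[idx] = ann.value
                if ann.context_text:
                    tokens.extend(
                        s.lower() for s, _, _ in tokenize(ann.context_text)
                    )
            vectors.append(
                FeatureVector(
                    study_id=study.doc_id,
                    arm_id=arm_id,
                    presence=presence,
                    numeric=numeric,
                    context_tokens=tokens,
                    outcome=outcomes[arm_id][1],
                )
            )
    return vectors


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, vectors: list[FeatureVector]) -> "Standardizer":
        numeric = np.array([v.numeric for v in vectors])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(numeric, axis=0)
            std = np.nanstd(numeric, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        std = np.where((std < 1e-12) | np.isnan(std), 1.0, std)
        return cls(mean=mean, std=std)

    def transform(self, vectors: list[FeatureVector]) -> np.ndarray:
        """Design matrix [presence | z-scored numeric | missing flags]."""
        rows = []
        for v in vectors:
            missing = np.isnan(v.numeric).astype(float)
            z = np.where(
                np.isnan(v.numeric), 0.0, (v.numeric - self.mean) / self.std
            )
            rows.append(np.concatenate([v.presence, z, missing]))
        return np.array(rows)


def design_matrix(
    vectors: list[FeatureVector], standardizer: Standardizer
) -> tuple[np.ndarray, np.ndarray]:
    X = standardizer.transform(vectors)
    y = np.array([v.outcome for v in vectors])
    return X, y


# ---------------------------------------------------------------------------
# co-occurrence graph and node embeddings


def build_cooccurrence_graph(studies: list[AnnotatedStudy]) -> nx.Graph:
    """Edge weight = number of documents in which both entities are annotated."""
    graph = nx.Graph()
    for study in studies:
        entities = sorted({a.entity_id for a in study.annotations})
        graph.add_nodes_from(entities)
        for i, a in enumerate(entities):
            for b in entities[i + 1 :]:
                if graph.has_edge(a, b):
                    graph[a][b]["weight"] += 1
                else:
                    graph.add_edge(a, b, weight=1)
    return graph


def _node2vec_walks(
    graph: nx.Graph, config: GraphEmbeddingConfig, rng: np.random.Generator
) -> list[list[str]]:
    nodes = sorted(graph.nodes)
    walks = []
    for _ in range(config.walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < config.walk_length:
                cur = walk[-1]
                nbrs = sorted(graph.neighbors(cur))
                if not nbrs:
                    break
                weights = np.array(
                    [graph[cur][x]["weight"] for x in nbrs], dtype=float
                )
                if len(walk) > 1:
                    prev = walk[-2]
                    bias = np.array(
                        [
                            1.0 / config.p
                            if x == prev
                            else (1.0 if graph.has_edge(prev, x) else 1.0 / config.q)
                            for x in nbrs
                        ]
                    )
                    weights = weights * bias
                probs = weights / weights.sum()
                walk.append(nbrs[rng.choice(len(nbrs), p=probs)])
            walks.append(walk)
    return walks


def learn_graph_embeddings(
    graph: nx.Graph, config: GraphEmbeddingConfig
) -> dict[str, np.ndarray]:
    """Node2vec-style embeddings: biased walks + skip-gram over the walks."""
    if graph.number_of_nodes() == 0:
        raise TrainingError("co-occurrence graph is empty")
    rng = np.random.default_rng(config.seed)
    walks = _node2vec_walks(graph, config, rng)
    return train_skipgram(
        walks,
        dim=config.dimensions,
        window=config.window,
        epochs=config.epochs,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# models


class GrandMeanModel:
    """Constant predictor: the mean of the training outcomes."""

    def __init__(self, mean: float):
        self.mean = float(mean)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.mean)


def fit_grand_mean(train_outcomes: np.ndarray) -> GrandMeanModel:
    train_outcomes = np.asarray(train_outcomes, dtype=float)
    if train_outcomes.size == 0:
        raise TrainingError("no training outcomes")
    return GrandMeanModel(train_outcomes.mean())


class LinearModel:
    def __init__(self, intercept: float, coef: np.ndarray):
        self.intercept = float(intercept)
        self.coef = coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef


def fit_linear_baseline(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Least-squares fit of the outcome on all features jointly.

    Rank-deficient designs get the minimum-norm solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise TrainingError("need at least 2 training rows")
    design = np.hstack([np.ones((len(X), 1)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearModel(intercept=beta[0], coef=beta[1:])


class RecurrentModel:
    """Stacked-LSTM regressor over schema-ordered per-entity embeddings."""

    def __init__(
        self,
        config: PredictionModelConfig,
        node_vectors: dict[str, np.ndarray],
        entity_order: list[str],
        text_vectors: dict[str, np.ndarray] | None,
    ):
        self.config = config
        self.node_vectors = node_vectors
        self.entity_order = entity_order
        self.text_vectors = text_vectors
        self._dim = config.graph.dimensions
        self._regressor = LSTMRegressor(
            layer_sizes=config.layer_sizes,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            seed=config.seed,
        )
        self._standardizer: Standardizer | None = None

    def _sequences(self, vectors: list[FeatureVector]) -> np.ndarray:
        assert self._standardizer is not None
        std = self._standardizer
        n_presence = len(vectors[0].presence) if vectors else 0
        use_text = self.config.feature_mode == "entities_plus_text"
        seqs = []
        for v in vectors:
            z = np.where(
                np.isnan(v.numeric), 0.0, (v.numeric - std.mean) / std.std
            )
            values = np.concatenate([v.presence, z])
            steps = []
            text_vec = None
            if use_text and self.text_vectors is not None:
                text_vec = mean_pool(
                    v.context_tokens, self.text_vectors, self.config.text_dim
                )
            for eid, val in zip(self.entity_order, values):
                node = self.node_vectors.get(eid, np.zeros(self._dim))
                step = node * val
                if text_vec is not None:
                    step = np.concatenate([step, text_vec])
                steps.append(step)
            seqs.append(np.array(steps))
        return np.array(seqs)

    def fit(self, vectors: list[FeatureVector]) -> "RecurrentModel":
        if not vectors:
            raise TrainingError("no training vectors")
        self._standardizer = Standardizer.fit(vectors)
        X = self._sequences(vectors)
        y = np.array([v.outcome for v in vectors])
        self._regressor.fit(X, y)
        return self

    def predict(self, vectors: list[FeatureVector]) -> np.ndarray:
        X = self._sequences(vectors)
        return np.clip(self._regressor.predict(X), 0.0, 100.0)


def fit_recurrent_model(
    train_vectors: list[FeatureVector],
    config: PredictionModelConfig,
    studies: list[AnnotatedStudy],
    schema: list[EntitySpec],
    outcome_entity_ids: tuple[str, ...] = DEFAULT_OUTCOME_ENTITIES,
) -> RecurrentModel:
    """Train the recurrent model on one training fold.

    Graph and text embeddings are learned from the training studies only.
    """
    graph = build_cooccurrence_graph(studies)
    if graph.number_of_nodes() == 0:
        raise TrainingError("no annotations to build the co-occurrence graph")
    node_vectors = learn_graph_embeddings(graph, config.graph)
    presence_ids, numeric_ids = feature_entities(schema, outcome_entity_ids)
    text_vectors = None
    if config.feature_mode == "entities_plus_text":
        sentences = [v.context_tokens for v in train_vectors if v.context_tokens]
        if sentences:
            text_vectors = train_skipgram(
                sentences, dim=config.text_dim, seed=config.seed
            )
    model = RecurrentModel(
        config, node_vectors, presence_ids + numeric_ids, text_vectors
    )
    return model.fit(train_vectors)


# ---------------------------------------------------------------------------
# evaluation


def rmse(predicted: np.ndarray, gold: np.ndarray) -> float:
    predicted = np.asarray(predicted, dtype=float)
    gold = np.asarray(gold, dtype=float)
    return float(np.sqrt(np.mean((predicted - gold) ** 2)))


def evaluate_prediction(
    studies: list[AnnotatedStudy],
    folds: CVFolds,
    schema: list[EntitySpec],
    model_families: tuple[str, ...] = MODEL_ROW_ORDER,
    seed: int = 0,
    outcome_entity_ids: tuple[str, ...] = DEFAULT_OUTCOME_ENTITIES,
    recurrent_config: PredictionModelConfig | None = None,
) -> RMSEReport:
    """Cross-validated RMSE per model family, mean over folds.

    Standardization statistics, co-occurrence graph and embeddings are
    fitted on each training fold only.
    """
    for fam in model_families:
        if fam not in MODEL_ROW_ORDER:
            raise ValidationError(f"unknown model family {fam!r}")
    families = [f for f in MODEL_ROW_ORDER if f in model_families]
    by_doc = {s.doc_id: s for s in studies}
    fold_rmse: dict[str, list[float]] = {f: [] for f in families}

    for fold_idx, test_ids in enumerate(folds.folds):
        test_set = set(test_ids)
        train_studies = [s for s in studies if s.doc_id not in test_set]
        test_studies = [by_doc[i] for i in test_ids if i in by_doc]
        assert not ({s.doc_id for s in train_studies} & test_set), "fold leakage"
        train_vecs = build_feature_vectors(
            train_studies, schema, outcome_entity_ids
        )
        test_vecs = build_feature_vectors(test_studies, schema, outcome_entity_ids)
        if not train_vecs or not test_vecs:
            continue
        standardizer = Standardizer.fit(train_vecs)
        X_train, y_train = design_matrix(train_vecs, standardizer)
        X_test, y_test = design_matrix(test_vecs, standardizer)
        fold_seed = seed * 1000 + fold_idx

        for fam in families:
            if fam == "grand_mean":
                preds = fit_grand_mean(y_train).predict(X_test)
            elif fam == "linear":
                preds = np.clip(
                    fit_linear_baseline(X_train, y_train).predict(X_test),
                    0.0,
                    100.0,
                )
            else:
                base = recurrent_config or PredictionModelConfig(
                    family=fam, feature_mode=fam
                )
                config = PredictionModelConfig(
                    family=fam,
                    layer_sizes=base.layer_sizes,
                    feature_mode=fam,
                    seed=fold_seed,
                    epochs=base.epochs,
                    learning_rate=base.learning_rate,
                    text_dim=base.text_dim,
                    graph=GraphEmbeddingConfig(
                        dimensions=base.graph.dimensions,
                        walks_per_node=base.graph.walks_per_node,
                        walk_length=base.graph.walk_length,
                        p=base.graph.p,
                        q=base.graph.q,
                        window=base.graph.window,
                        epochs=base.graph.epochs,
                        seed=fold_seed,
                    ),
                )
                model = fit_recurrent_model(
                    train_vecs, config, train_studies, schema, outcome_entity_ids
                )
                preds = model.predict(test_vecs)
            fold_rmse[fam].append(rmse(preds, y_test))

    mean_rmse = {
        fam: float(np.mean(scores)) if scores else float("nan")
        for fam, scores in fold_rmse.items()
    }
    return RMSEReport(
        mean_rmse=mean_rmse, fold_rmse=fold_rmse, seed=seed, k=folds.k
    )
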