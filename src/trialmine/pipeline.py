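"""End-to-end orchestration: gold tag sequences for training, tagging +
arm resolution into structured studies, extraction scoring and the
cross-validated prediction experiment.

Extraction evaluation and prediction evaluation are deliberately
independent: the prediction experiment consumes gold annotations, never
tagger output, so extraction errors cannot confound the prediction
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .arms import (
    ArmResolutionConfig,
    associate_entities,
    cluster_arm_mentions,
    detect_arm_count,
)
from .errors import TrainingError
from .evaluate import (
    CVFolds,
    EvalReport,
    arm_assignment_accuracy,
    make_cv_folds,
    match_annotations,
    score_counts,
    summarize,
)
from .ingest import Document
from .predict import (
    MODEL_ROW_ORDER,
    PredictionModelConfig,
    RMSEReport,
    evaluate_prediction,
)
from .schema import (
    ARM_NAME,
    WHOLE_STUDY,
    AnnotatedStudy,
    Annotation,
    EntitySpec,
    normalize_value,
    schema_index,
)
from .simulate import GoldStudy
from .tagging import (
    GazetteerTagger,
    Mention,
    StatisticalTagger,
    TagSequence,
    encode_bio,
    tag_document,
    tokenize,
)


def gold_tag_sequences(gold: GoldStudy) -> list[TagSequence]:
    """BIO-tagged sentences (body and pseudo) from one gold study.

    Entity annotations become mentions labelled with their entity id; arm
    mentions get the reserved ARM_NAME label.  Table annotations are
    aligned with their pseudo-sentences positionally (both are emitted in
    row-major cell order).
    """
    study, document = gold.study, gold.document
    sequences: list[TagSequence] = []
    spans = [
        (ann.entity_id, ann.span)
        for ann in study.annotations
        if ann.span is not None
    ]
    arm_spans = [
        (m.surface, m.span)
        for arm in study.arms
        for m in arm.mentions
        if m.span is not None
    ]
    for start, end in document.sentences:
        text = document.body_text[start:end]
        mentions = [
            Mention(label=eid, start=s - start, end=e - start)
            for eid, (s, e) in spans
            if start <= s and e <= end
        ] + [
            Mention(label=ARM_NAME, start=s - start, end=e - start)
            for _, (s, e) in arm_spans
            if start <= s and e <= end
        ]
        sequences.append(encode_bio(tokenize(text), mentions))

    table_anns = [a for a in study.annotations if a.span is None]
    for ps, ann in zip(document.pseudo_sentences, table_anns):
        text = ps.text
        cell = ann.raw_text
        cell_start = len(text) - len(" .") - len(cell)
        mentions = [Mention(label=ann.entity_id, start=cell_start,
                            end=cell_start + len(cell))]
        row_header = text.split(" : ", 1)[0]
        if row_header and row_header in {
            m.surface for arm in study.arms for m in arm.mentions
        }:
            mentions.append(Mention(label=ARM_NAME, start=0, end=len(row_header)))
        sequences.append(encode_bio(tokenize(text), mentions))
    return sequences


def corpus_to_tag_sequences(corpus: list[GoldStudy]) -> list[TagSequence]:
    out: list[TagSequence] = []
    for gold in corpus:
        out.extend(gold_tag_sequences(gold))
    return out


# ---------------------------------------------------------------------------
# extraction


def extract_study(
    model: GazetteerTagger | StatisticalTagger,
    document: Document,
    schema: list[EntitySpec],
    arm_config: ArmResolutionConfig | None = None,
) -> AnnotatedStudy:
    """Tag a document, resolve arms, and emit a structured study."""
    mentions = tag_document(model, document)
    return _studies_from_mentions(document, mentions, schema, arm_config)


def _studies_from_mentions(
    document: Document,
    mentions: list[Mention],
    schema: list[EntitySpec],
    arm_config: ArmResolutionConfig | None = None,
) -> AnnotatedStudy:
    arm_config = arm_config or ArmResolutionConfig()
    by_id = schema_index(schema)
    arm_mentions = [m for m in mentions if m.label == ARM_NAME]
    # study-scoped entities never attach to arms (schema arm_scoped flag)
    scoped = {eid for eid, spec in by_id.items() if spec.arm_scoped}
    entity_mentions = [m for m in mentions if m.label in by_id]

    arms = []
    if arm_mentions:
        n = detect_arm_count(document.body_text)
        distinct = len({m.text for m in arm_mentions})
        if n is not None:
            n = min(n, distinct)
        arms = cluster_arm_mentions(arm_mentions, n, arm_config)
    assignments = associate_entities(
        document, entity_mentions, arm_mentions, arms, arm_config
    )

    def context_for(m: Mention) -> str:
        if m.context_id != "body":
            for idx, ps in enumerate(document.pseudo_sentences):
                if m.context_id == f"table:{ps.table_id}:{idx}":
                    return ps.text
            return ""
        for start, end in document.sentences:
            if start <= m.start < end:
                return document.body_text[start:end]
        return ""

    annotations = []
    for m, assignment in zip(entity_mentions, assignments):
        spec = by_id[m.label]
        value = None
        if spec.has_value:
            try:
                value = normalize_value(m.text, spec)
            except Exception:
                continue  # value-kind mention without a numeral: drop
        annotations.append(
            Annotation(
                doc_id=document.doc_id,
                entity_id=m.label,
                span=(m.start, m.end) if m.source == "body" else None,
                raw_text=m.text,
                context_text=context_for(m),
                value=value,
                arm_ref=assignment.target if m.label in scoped else WHOLE_STUDY,
            )
        )
    study = AnnotatedStudy(
        doc_id=document.doc_id,
        text=document.body_text,
        arms=arms,
        annotations=annotations,
    )
    study.validate()
    return study


@dataclass
class ExtractionResult:
    predicted: list[AnnotatedStudy]
    report: EvalReport | None = None
    arm_accuracy: float | None = None
    whole_study_fraction: float = 0.0


def run_extraction(
    model: GazetteerTagger | StatisticalTagger,
    documents: list[Document],
    schema: list[EntitySpec],
    arm_config: ArmResolutionConfig | None = None,
    gold: list[AnnotatedStudy] | None = None,
    criterion: str = "entity",
) -> ExtractionResult:
    """Tag and arm-resolve each document; score against gold if supplied."""
    if model is None:
        raise TrainingError(
            "no tagger model supplied; train one with train_tagger or the "
            "train-tagger subcommand first"
        )
    predicted = [
        extract_study(model, doc, schema, arm_config) for doc in documents
    ]
    n_total = sum(len(s.annotations) for s in predicted)
    n_whole = sum(
        1
        for s in predicted
        for a in s.annotations
        if a.arm_ref == WHOLE_STUDY
    )
    result = ExtractionResult(
        predicted=predicted,
        whole_study_fraction=n_whole / n_total if n_total else 0.0,
    )
    if gold is not None:
        counts = match_annotations(gold, predicted, schema, criterion)
        result.report = summarize(score_counts(counts))
        result.arm_accuracy = arm_assignment_accuracy(gold, predicted)
    return result


# ---------------------------------------------------------------------------
# prediction experiment


@dataclass
class PredictionExperimentConfig:
    k: int = 5
    seed: int = 0
    model_families: tuple[str, ...] = MODEL_ROW_ORDER
    recurrent: PredictionModelConfig = field(
        default_factory=PredictionModelConfig
    )


def run_prediction_experiment(
    studies: list[AnnotatedStudy],
    schema: list[EntitySpec],
    config: PredictionExperimentConfig | None = None,
) -> RMSEReport:
    """Five-fold CV comparison of the configured model families on gold data."""
    config = config or PredictionExperimentConfig()
    ids = [s.doc_id for s in studies]
    folds: CVFolds = make_cv_folds(ids, config.k, config.seed)
    return evaluate_prediction(
        studies,
        folds,
        schema,
        model_families=config.model_families,
        seed=config.seed,
        recurrent_config=config.recurrent,
    )
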