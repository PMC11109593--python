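"""Extraction scoring: instance matching, precision/recall/F1, summary
tables, human benchmarking, Krippendorff's alpha and cross-validation folds.

The default matching criterion is document-level: a predicted instance is a
true positive iff gold contains an unmatched instance with the same
(doc_id, entity_id) and — for value-carrying entities — an equal normalized
value.  A strict mode additionally requires span equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .errors import EvaluationError, ValidationError
from .schema import AnnotatedStudy, EntitySpec, schema_index


@dataclass
class EvalCounts:
    per_entity: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def add(self, entity_id: str, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
        a, b, c = self.per_entity.get(entity_id, (0, 0, 0))
        self.per_entity[entity_id] = (a + tp, b + fp, c + fn)

    def totals(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.per_entity.values())
        fp = sum(v[1] for v in self.per_entity.values())
        fn = sum(v[2] for v in self.per_entity.values())
        return tp, fp, fn


@dataclass
class EntityScore:
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    """Per-entity F1 table with mean/median/max/min summary rows."""

    per_entity: dict[str, EntityScore]
    summary: dict[str, float]
    benchmark: dict[str, EntityScore] | None = None
    benchmark_summary: dict[str, float] | None = None


@dataclass
class AgreementReport:
    alpha: float
    n_items: int
    degenerate: bool = False


@dataclass
class CVFolds:
    folds: list[list[str]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


# ---------------------------------------------------------------------------
# matching and scores


def _instance_key(ann, spec: EntitySpec, strict: bool) -> tuple:
    if strict:
        return (ann.doc_id, ann.entity_id, ann.span, ann.value)
    if spec.has_value:
        return (ann.doc_id, ann.entity_id, ann.value)
    return (ann.doc_id, ann.entity_id)


def match_annotations(
    gold: Sequence[AnnotatedStudy],
    predicted: Sequence[AnnotatedStudy],
    schema: Sequence[EntitySpec],
    criterion: str = "entity",
) -> EvalCounts:
    """Count TP/FP/FN per entity via greedy 1-to-1 matching in document order."""
    if criterion not in ("entity", "strict"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    strict = criterion == "strict"
    by_id = schema_index(schema)
    counts = EvalCounts()
    gold_keys: dict[tuple, int] = {}
    for study in gold:
        for ann in study.annotations:
            spec = by_id.get(ann.entity_id)
            if spec is None:
                raise ValidationError(f"unknown entity_id {ann.entity_id!r}")
            key = _instance_key(ann, spec, strict)
            gold_keys[key] = gold_keys.get(key, 0) + 1

    for study in predicted:
        for ann in study.annotations:
            spec = by_id.get(ann.entity_id)
            if spec is None:
                raise ValidationError(f"unknown entity_id {ann.entity_id!r}")
            key = _instance_key(ann, spec, strict)
            if gold_keys.get(key, 0) > 0:
                gold_keys[key] -= 1
                counts.add(ann.entity_id, tp=1)
            else:
                counts.add(ann.entity_id, fp=1)

    for key, remaining in gold_keys.items():
        if remaining > 0:
            counts.add(key[1], fn=remaining)
    return counts


def precision_recall_f1(tp: int, fp: int, fn: int) -> EntityScore:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0 on empty denominators."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return EntityScore(precision=p, recall=r, f1=f1)


def score_counts(counts: EvalCounts) -> dict[str, EntityScore]:
    return {
        eid: precision_recall_f1(*tpfpfn)
        for eid, tpfpfn in sorted(counts.per_entity.items())
    }


def micro_f1(counts: EvalCounts) -> float:
    return precision_recall_f1(*counts.totals()).f1


def summarize(
    scores: dict[str, EntityScore],
    benchmark: dict[str, EntityScore] | None = None,
) -> EvalReport:
    """Mean/median/max/min of per-entity F1, optionally with a second column."""
    if not scores:
        raise EvaluationError("no entities to summarize")

    def stats(table: dict[str, EntityScore]) -> dict[str, float]:
        f1s = np.array([s.f1 for s in table.values()])
        return {
            "mean": float(f1s.mean()),
            "median": float(np.median(f1s)),
            "maximum": float(f1s.max()),
            "minimum": float(f1s.min()),
        }

    return EvalReport(
        per_entity=scores,
        summary=stats(scores),
        benchmark=benchmark,
        benchmark_summary=stats(benchmark) if benchmark else None,
    )


def human_benchmark(
    annotator_a: Sequence[AnnotatedStudy],
    annotator_b: Sequence[AnnotatedStudy],
    schema: Sequence[EntitySpec],
    criterion: str = "entity",
) -> EvalReport:
    """Score annotator B against annotator A taken as the criterion."""
    docs_a = {s.doc_id for s in annotator_a}
    docs_b = {s.doc_id for s in annotator_b}
    if docs_a and docs_b and not (docs_a & docs_b):
        raise EvaluationError("annotators cover disjoint document sets")
    counts = match_annotations(annotator_a, annotator_b, schema, criterion)
    return summarize(score_counts(counts))


def arm_assignment_accuracy(
    gold: Sequence[AnnotatedStudy],
    predicted: Sequence[AnnotatedStudy],
    arm_label_map: dict[str, dict[str, str]] | None = None,
) -> float:
    """Fraction of matched entity instances assigned to the correct arm.

    Predicted arm ids are compared through arm labels: a predicted
    assignment is correct when its arm's label is one of the gold arm's
    mention surfaces (or via an explicit per-document label map).
    """
    gold_by_doc = {s.doc_id: s for s in gold}
    total = correct = 0
    for pstudy in predicted:
        gstudy = gold_by_doc.get(pstudy.doc_id)
        if gstudy is None:
            continue
        plabels = {a.arm_id: a.label for a in pstudy.arms}
        gold_surface_to_arm: dict[str, str] = {}
        for garm in gstudy.arms:
            for gm in garm.mentions:
                gold_surface_to_arm.setdefault(gm.surface, garm.arm_id)
        gold_anns = {
            (ann.entity_id, ann.span, ann.value): ann.arm_ref
            for ann in gstudy.annotations
        }
        for ann in pstudy.annotations:
            gold_ref = gold_anns.get((ann.entity_id, ann.span, ann.value))
            if gold_ref is None:
                continue
            total += 1
            if ann.arm_ref == gold_ref:
                correct += 1
                continue
            pred_label = plabels.get(ann.arm_ref)
            if arm_label_map and pstudy.doc_id in arm_label_map:
                mapped = arm_label_map[pstudy.doc_id].get(ann.arm_ref)
            else:
                mapped = (
                    gold_surface_to_arm.get(pred_label)
                    if pred_label is not None
                    else None
                )
            if mapped == gold_ref:
                correct += 1
    return correct / total if total else 0.0


# ---------------------------------------------------------------------------
# Krippendorff's alpha (nominal, two coders)


def krippendorff_alpha(
    codes_a: Sequence[Hashable], codes_b: Sequence[Hashable]
) -> AgreementReport:
    """Nominal-level Krippendorff's alpha from the coincidence matrix.

    alpha = 1 - observed disagreement / expected disagreement.  When only a
    single category occurs, expected disagreement is 0 and alpha is
    undefined; it is reported as 1.0 with a warning.
    """
    if len(codes_a) != len(codes_b):
        raise EvaluationError("coders must code the same items")
    if len(codes_a) < 2:
        raise EvaluationError("need at least 2 items")

    categories = sorted(set(codes_a) | set(codes_b), key=repr)
    cat_index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    coincidence = np.zeros((k, k))
    for a, b in zip(codes_a, codes_b):
        i, j = cat_index[a], cat_index[b]
        # each item contributes its 2 ordered coder pairs, each weight 1/(m-1)=1
        coincidence[i, j] += 1
        coincidence[j, i] += 1

    n_c = coincidence.sum(axis=1)
    n_total = coincidence.sum()
    if k == 1:
        warnings.warn("alpha undefined: only one category present")
        return AgreementReport(alpha=1.0, n_items=len(codes_a), degenerate=True)

    observed_disagreement = n_total - np.trace(coincidence)
    expected_disagreement = (n_total**2 - (n_c**2).sum()) / (n_total - 1)
    if expected_disagreement == 0:
        warnings.warn("alpha undefined: no expected disagreement")
        return AgreementReport(alpha=1.0, n_items=len(codes_a), degenerate=True)
    alpha = 1.0 - observed_disagreement / expected_disagreement
    return AgreementReport(alpha=float(alpha), n_items=len(codes_a))


# ---------------------------------------------------------------------------
# cross-validation folds


def make_cv_folds(
    study_ids: Sequence[str], k: int, seed: int
) -> CVFolds:
    """Seeded shuffle then round-robin split into k disjoint test folds."""
    ids = list(study_ids)
    if k > len(ids):
        raise EvaluationError(f"k={k} exceeds number of studies {len(ids)}")
    if k < 1:
        raise EvaluationError("k must be >= 1")
    if k == 1:
        warnings.warn("k=1 gives a single degenerate fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return CVFolds(folds=folds, seed=seed)


def report_to_dict(report: EvalReport) -> dict:
    out: dict = {
        "per_entity": {
            eid: {
                "precision": s.precision,
                "recall": s.recall,
                "f1": s.f1,
            }
            for eid, s in report.per_entity.items()
        },
        "summary": report.summary,
    }
    if report.benchmark_summary is not None:
        out["benchmark_summary"] = report.benchmark_summary
    return out
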