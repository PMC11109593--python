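"""Entity schema, annotation data model and JSON-lines corpus I/O.

The extraction schema is a flat list of :class:`EntitySpec` records, one per
extraction target.  Three kinds of target exist:

``presence_absence``
    the target is a yes/no flag (e.g. whether a behaviour-change technique
    was used in an arm);
``value``
    the target carries a single decimal number (e.g. mean age in years);
``complex_component``
    a numeric sub-field of a parent class (e.g. the percentage belonging to
    one ethnic group), linked via ``parent_id``.

Annotations ground schema entities in a document: a character span, the
verbatim text, an optional normalized value and a link to a study arm (or
the whole study).  Studies are serialized one-per-line as JSON.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import NormalizationError, SchemaError, ValidationError

#: Sentinel arm reference for study-level annotations.
WHOLE_STUDY = "WHOLE_STUDY"

#: Reserved mention label for study-arm names (not part of the schema).
ARM_NAME = "ARM_NAME"

_NUMERAL_RE = re.compile(r"\d+(?:\.\d+)?")


class EntityKind(str, Enum):
    presence_absence = "presence_absence"
    value = "value"
    complex_component = "complex_component"


@dataclass(frozen=True)
class EntitySpec:
    """One extraction target."""

    entity_id: str
    name: str
    kind: EntityKind
    parent_id: str | None = None
    value_unit: str | None = None
    arm_scoped: bool = True

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise SchemaError("entity_id must be non-empty")
        kind = EntityKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is EntityKind.complex_component and not self.parent_id:
            raise SchemaError(
                f"{self.entity_id}: complex_component requires a parent_id"
            )
        if kind is EntityKind.presence_absence and self.value_unit:
            raise SchemaError(
                f"{self.entity_id}: presence_absence entities carry no value_unit"
            )

    @property
    def has_value(self) -> bool:
        return self.kind in (EntityKind.value, EntityKind.complex_component)


@dataclass
class Annotation:
    """A grounded entity instance inside one document."""

    doc_id: str
    entity_id: str
    span: tuple[int, int] | None = None
    raw_text: str = ""
    context_text: str = ""
    value: float | None = None
    arm_ref: str = WHOLE_STUDY

    def __post_init__(self) -> None:
        if self.span is not None:
            start, end = self.span
            if not (0 <= start < end):
                raise ValidationError(
                    f"invalid span {self.span!r} for {self.entity_id}"
                )
            self.span = (int(start), int(end))


@dataclass
class ArmMention:
    surface: str
    span: tuple[int, int] | None = None


@dataclass
class Arm:
    """A clustered study group: canonical label plus its surface mentions."""

    arm_id: str
    label: str
    mentions: list[ArmMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mentions:
            self.mentions = [ArmMention(self.label)]
        surfaces = {m.surface for m in self.mentions}
        if self.label not in surfaces:
            raise ValidationError(
                f"arm {self.arm_id}: label {self.label!r} is not a member mention"
            )


@dataclass
class OutcomeRecord:
    """Per-arm cessation percentage — the prediction target."""

    arm_id: str
    entity_id: str
    value: float


@dataclass
class AnnotatedStudy:
    """One study's gold or predicted extraction."""

    doc_id: str
    text: str = ""
    arms: list[Arm] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    outcomes: list[OutcomeRecord] = field(default_factory=list)

    def validate(self, schema: Sequence[EntitySpec] | None = None) -> None:
        arm_ids = {a.arm_id for a in self.arms}
        seen_outcomes: set[tuple[str, str]] = set()
        for rec in self.outcomes:
            key = (rec.arm_id, rec.entity_id)
            if key in seen_outcomes:
                raise ValidationError(
                    f"{self.doc_id}: duplicate outcome for {key}"
                )
            seen_outcomes.add(key)
        by_id = {s.entity_id: s for s in schema} if schema is not None else None
        for ann in self.annotations:
            if ann.arm_ref != WHOLE_STUDY and ann.arm_ref not in arm_ids:
                raise ValidationError(
                    f"{self.doc_id}: annotation references unknown arm "
                    f"{ann.arm_ref!r}"
                )
            if ann.span is not None:
                start, end = ann.span
                if end > len(self.text):
                    raise ValidationError(
                        f"{self.doc_id}: span {ann.span} beyond text length "
                        f"{len(self.text)}"
                    )
                if self.text and ann.raw_text != self.text[start:end]:
                    raise ValidationError(
                        f"{self.doc_id}: raw_text {ann.raw_text!r} does not "
                        f"match text at {ann.span}"
                    )
            if by_id is not None:
                spec = by_id.get(ann.entity_id)
                if spec is None:
                    raise ValidationError(
                        f"{self.doc_id}: unknown entity_id {ann.entity_id!r}"
                    )
                if spec.has_value != (ann.value is not None):
                    raise ValidationError(
                        f"{self.doc_id}: entity {ann.entity_id} of kind "
                        f"{spec.kind.value} has value={ann.value!r}"
                    )


# ---------------------------------------------------------------------------
# schema loading


def default_schema_path() -> Path:
    """Path of the bundled 70-entity extraction schema."""
    return Path(__file__).parent / "data" / "schema70.csv"


def load_entity_schema(path: str | Path) -> list[EntitySpec]:
    """Load an entity schema from CSV or JSON.

    CSV columns: entity_id, name, kind, parent_id, value_unit, arm_scoped.
    Duplicate entity ids are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: expected a JSON array of entities")
        records = [(i + 1, row) for i, row in enumerate(rows)]
    else:
        records = []
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            required = {"entity_id", "name", "kind"}
            missing = required - set(reader.fieldnames)
            if missing:
                raise SchemaError(
                    f"{path}: line 1: missing columns {sorted(missing)}"
                )
            for row in reader:
                records.append((reader.line_num, row))

    specs: list[EntitySpec] = []
    seen: set[str] = set()
    for line_num, row in records:
        try:
            spec = EntitySpec(
                entity_id=str(row["entity_id"]).strip(),
                name=str(row.get("name", "")).strip(),
                kind=EntityKind(str(row["kind"]).strip()),
                parent_id=_opt(row.get("parent_id")),
                value_unit=_opt(row.get("value_unit")),
                arm_scoped=_parse_bool(row.get("arm_scoped", True)),
            )
        except (KeyError, ValueError, SchemaError) as exc:
            raise SchemaError(f"{path}: line {line_num}: {exc}") from exc
        if spec.entity_id in seen:
            raise SchemaError(
                f"{path}: line {line_num}: duplicate entity_id "
                f"{spec.entity_id!r}"
            )
        seen.add(spec.entity_id)
        specs.append(spec)

    ids = {s.entity_id for s in specs}
    for s in specs:
        if s.parent_id is not None and s.parent_id not in ids:
            raise SchemaError(
                f"{path}: {s.entity_id}: unknown parent_id {s.parent_id!r}"
            )
    _check_forest(specs)
    return specs


def _opt(value: object) -> str | None:
    if value is None:
        return None
    text = str(value).strip()
    return text or None


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n", ""):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _check_forest(specs: Sequence[EntitySpec]) -> None:
    parent = {s.entity_id: s.parent_id for s in specs}
    for start in parent:
        seen = set()
        node: str | None = start
        while node is not None:
            if node in seen:
                raise SchemaError(f"parent_id cycle involving {node!r}")
            seen.add(node)
            node = parent.get(node)


def schema_index(schema: Sequence[EntitySpec]) -> dict[str, EntitySpec]:
    return {s.entity_id: s for s in schema}


# ---------------------------------------------------------------------------
# value normalization


def normalize_value(raw_text: str, spec: EntitySpec) -> float:
    """Parse the first decimal numeral from ``raw_text``.

    Trailing unit words ("44.5 years" -> 44.5) are ignored.  Word numerals
    are out of scope and raise :class:`NormalizationError`.
    """
    if not spec.has_value:
        raise ValidationError(
            f"{spec.entity_id} is {spec.kind.value}; it carries no value"
        )
    match = _NUMERAL_RE.search(raw_text)
    if match is None:
        raise NormalizationError(f"no decimal numeral in {raw_text!r}")
    return float(match.group(0))


# ---------------------------------------------------------------------------
# JSON-lines corpus I/O


def study_to_dict(study: AnnotatedStudy) -> dict:
    return {
        "doc_id": study.doc_id,
        "text": study.text,
        "arms": [
            {
                "arm_id": a.arm_id,
                "label": a.label,
                "mentions": [
                    {"surface": m.surface, "span": list(m.span) if m.span else None}
                    for m in a.mentions
                ],
            }
            for a in study.arms
        ],
        "annotations": [
            {
                "doc_id": ann.doc_id,
                "entity_id": ann.entity_id,
                "span": list(ann.span) if ann.span else None,
                "raw_text": ann.raw_text,
                "context_text": ann.context_text,
                "value": ann.value,
                "arm_ref": ann.arm_ref,
            }
            for ann in study.annotations
        ],
        "outcomes": [asdict(o) for o in study.outcomes],
    }


def study_from_dict(obj: dict) -> AnnotatedStudy:
    study = AnnotatedStudy(
        doc_id=obj["doc_id"],
        text=obj.get("text", ""),
        arms=[
            Arm(
                arm_id=a["arm_id"],
                label=a["label"],
                mentions=[
                    ArmMention(
                        surface=m["surface"],
                        span=tuple(m["span"]) if m.get("span") else None,
                    )
                    for m in a.get("mentions", [])
                ],
            )
            for a in obj.get("arms", [])
        ],
        annotations=[
            Annotation(
                doc_id=ann["doc_id"],
                entity_id=ann["entity_id"],
                span=tuple(ann["span"]) if ann.get("span") else None,
                raw_text=ann.get("raw_text", ""),
                context_text=ann.get("context_text", ""),
                value=ann.get("value"),
                arm_ref=ann.get("arm_ref", WHOLE_STUDY),
            )
            for ann in obj.get("annotations", [])
        ],
        outcomes=[
            OutcomeRecord(
                arm_id=o["arm_id"],
                entity_id=o["entity_id"],
                value=float(o["value"]),
            )
            for o in obj.get("outcomes", [])
        ],
    )
    study.validate()
    return study


def write_annotations(
    studies: Iterable[AnnotatedStudy], path: str | Path
) -> None:
    """Write studies as JSON-lines, one study per line (UTF-8)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for study in studies:
            study.validate()
            fh.write(json.dumps(study_to_dict(study), ensure_ascii=False))
            fh.write("\n")


def read_annotations(path: str | Path) -> list[AnnotatedStudy]:
    """Read a JSON-lines corpus written by :func:`write_annotations`."""
    studies = []
    with Path(path).open(encoding="utf-8") as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}: line {line_num}: {exc}") from exc
            studies.append(study_from_dict(obj))
    return studies
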