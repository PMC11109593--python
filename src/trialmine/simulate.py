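"""Synthetic gold-annotated trial reports.

Generates templated study reports with a known number of arms, known
entity values, optional result tables, and per-arm outcomes drawn from an
additive linear model

    outcome = b0 + sum(beta_e * presence_e) + sum(gamma_e * value_e) + noise

clipped to [0, 100].  Every emitted entity and arm-name mention is recorded
as a gold annotation with exact character spans, so taggers, arm resolution
and the prediction experiment are all testable offline.

Hard cases from real reports are toggles: synonymous arm mentions,
entities reported only in tables, and arm mentions placed beyond the
association window (``arm_mention_placement="far"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import TrainingError, ValidationError
from .ingest import Document, Table, build_document
from .schema import (
    WHOLE_STUDY,
    AnnotatedStudy,
    Annotation,
    Arm,
    ArmMention,
    OutcomeRecord,
)

# surface phrase emitted (and annotated) for each presence entity
PRESENCE_PHRASES: dict[str, str] = {
    "bct_goal_setting": "goal setting",
    "bct_problem_solving": "problem solving",
    "bct_self_monitoring": "self monitoring",
    "bct_social_support": "social support",
    "drug_nrt": "nicotine replacement therapy",
    "drug_varenicline": "varenicline",
    "delivery_phone": "telephone counselling",
    "delivery_group": "group sessions",
}

# study-level presence entities: entity -> (prefix, annotated phrase, suffix)
STUDY_PRESENCE_TEMPLATES: dict[str, tuple[str, str, str]] = {
    "setting_primary_care": (
        "The study was conducted in ",
        "primary care clinics",
        " .",
    ),
    "verification_biochemical": (
        "Abstinence was confirmed by ",
        "biochemical verification",
        " .",
    ),
}

# arm-scoped numeric entities: entity -> (prefix after arm, unit, low, high, decimals)
ARM_VALUE_TEMPLATES: dict[str, tuple[str, str, float, float, int]] = {
    "n_randomised": (" enrolled ", "participants", 50, 300, 0),
    "sessions_count": (" attended ", "sessions", 4, 12, 0),
    "intervention_weeks": (" lasted ", "weeks", 6, 26, 0),
}

# study-level numeric entities: entity -> (prefix, unit, suffix, low, high, decimals)
STUDY_VALUE_TEMPLATES: dict[str, tuple[str, str, str, float, float, int]] = {
    "mean_age": ("Mean age of participants was ", "years", " .", 30, 60, 1),
    "mean_cigs_per_day": (
        "On average participants smoked ",
        "cigarettes",
        " per day .",
        10,
        25,
        1,
    ),
}

DEFAULT_ARM_LEXICON: list[list[str]] = [
    ["intervention", "intervention group"],
    ["control", "control group"],
    ["patch", "patch group"],
    ["gum", "gum group"],
]

_FILLER_SENTENCES = [
    "The protocol was registered prospectively and approved by an ethics committee .",
    "Written informed consent was obtained before enrolment .",
    "Baseline assessments took place during an initial visit .",
    "Follow up data were collected by blinded assessors at scheduled visits .",
    "Analyses followed the intention to treat principle throughout the trial .",
    "Missing outcome data were treated as continued smoking .",
]

_WORD_NUMERALS = {2: "two", 3: "three", 4: "four"}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 10
    arm_count_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.4}
    )
    inclusion_probs: dict[str, float] = field(default_factory=dict)
    arm_lexicon: list[list[str]] = field(
        default_factory=lambda: [list(s) for s in DEFAULT_ARM_LEXICON]
    )
    synonym_noise: bool = False
    arm_mention_placement: str = "near"  # "near" | "far"
    table_probability: float = 0.0
    table_entities: tuple[str, ...] = ("sessions_count",)
    table_only_entities: tuple[str, ...] = ()
    outcome_entity: str = "outcome_abstinence_12m"
    intercept: float = 30.0
    presence_effects: dict[str, float] = field(default_factory=dict)
    numeric_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 5.0
    use_word_numerals: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for p in self.inclusion_probs.values():
            if not 0 <= p <= 1:
                raise ValidationError("inclusion probabilities must be in [0,1]")
        if self.arm_mention_placement not in ("near", "far"):
            raise ValidationError(
                f"unknown placement {self.arm_mention_placement!r}"
            )
        if not 0 <= self.table_probability <= 1:
            raise ValidationError("table_probability must be in [0,1]")

    def inclusion(self, entity_id: str, default: float = 0.5) -> float:
        return self.inclusion_probs.get(entity_id, default)


@dataclass
class GoldStudy:
    study: AnnotatedStudy
    document: Document
    linear_pred: dict[str, float]  # per arm, noise-free and unclipped
    tables: list[Table] = field(default_factory=list)


class _DocBuilder:
    """Accumulates sentences while recording exact character spans."""

    def __init__(self) -> None:
        self.text = ""
        self.annotations: list[tuple[str, tuple[int, int], str, float | None, str, str]] = []
        self.arm_mentions: list[tuple[str, tuple[int, int]]] = []

    def sentence(self, segments: list) -> None:
        """segments: str | ("entity", eid, surface, value, arm_ref)
        | ("arm", surface)."""
        if self.text:
            self.text += " "
        sent_start = len(self.text)
        pending: list[tuple[str, tuple[int, int], str, float | None, str]] = []
        for seg in segments:
            if isinstance(seg, str):
                self.text += seg
                continue
            kind = seg[0]
            start = len(self.text)
            surface = seg[2] if kind == "entity" else seg[1]
            self.text += surface
            span = (start, len(self.text))
            if kind == "entity":
                _, eid, _, value, arm_ref = seg
                pending.append((eid, span, surface, value, arm_ref))
            else:
                self.arm_mentions.append((surface, span))
        context = self.text[sent_start:]
        for eid, span, surface, value, arm_ref in pending:
            self.annotations.append((eid, span, surface, value, arm_ref, context))


def _fmt(value: float, decimals: int) -> str:
    if decimals == 0:
        return str(int(round(value)))
    return f"{value:.{decimals}f}"


def generate_study(config: GeneratorConfig, study_seed: int) -> GoldStudy:
    """Render one templated study with gold annotations and known outcomes."""
    rng = np.random.default_rng([config.seed, study_seed])
    doc_id = f"study_{study_seed:04d}"

    counts = sorted(config.arm_count_weights)
    weights = np.array([config.arm_count_weights[c] for c in counts], dtype=float)
    n_arms = int(rng.choice(counts, p=weights / weights.sum()))
    if n_arms > len(config.arm_lexicon):
        raise TrainingError("arm lexicon smaller than sampled arm count")
    lexicon = [config.arm_lexicon[i] for i in range(n_arms)]

    def arm_surface(arm_idx: int) -> str:
        synonyms = lexicon[arm_idx]
        if config.synonym_noise and len(synonyms) > 1:
            return synonyms[int(rng.integers(len(synonyms)))]
        return synonyms[0]

    far = config.arm_mention_placement == "far"
    builder = _DocBuilder()

    builder.sentence(
        [f"This randomised controlled trial evaluated smoking cessation support ."]
    )

    # arm-count sentence + arm introductions
    numeral = (
        _WORD_NUMERALS.get(n_arms, str(n_arms))
        if config.use_word_numerals and bool(rng.integers(2))
        else str(n_arms)
    )
    intro: list = [f"Participants were randomised into {numeral} groups : "]
    for i in range(n_arms):
        if i > 0:
            intro.append(" and " if i == n_arms - 1 else " , ")
        intro.append("the ")
        intro.append(("arm", lexicon[i][0]))
        intro.append(" condition")
    intro.append(" .")
    builder.sentence(intro)

    # study-level entities
    numeric_values: dict[str, float] = {}
    for eid, (prefix, unit, suffix, low, high, dec) in STUDY_VALUE_TEMPLATES.items():
        if rng.random() < config.inclusion(eid, 1.0):
            value = float(_fmt(rng.uniform(low, high), dec))
            builder.sentence(
                [
                    prefix,
                    ("entity", eid, f"{_fmt(value, dec)} {unit}", value, WHOLE_STUDY),
                    suffix,
                ]
            )
            numeric_values[eid] = value
    for eid, (prefix, phrase, suffix) in STUDY_PRESENCE_TEMPLATES.items():
        if rng.random() < config.inclusion(eid):
            builder.sentence(
                [prefix, ("entity", eid, phrase, None, WHOLE_STUDY), suffix]
            )

    if far:  # push arm mentions beyond any reasonable window
        for sent in _FILLER_SENTENCES:
            builder.sentence([sent])
        for sent in _FILLER_SENTENCES:
            builder.sentence([sent])

    # per-arm entities
    arm_ids = [f"arm_{i + 1}" for i in range(n_arms)]
    presence: dict[str, set[str]] = {a: set() for a in arm_ids}
    arm_numeric: dict[str, dict[str, float]] = {a: {} for a in arm_ids}
    table_rows: dict[str, dict[str, str]] = {a: {} for a in arm_ids}

    for i, arm_id in enumerate(arm_ids):
        for eid, phrase in PRESENCE_PHRASES.items():
            if rng.random() >= config.inclusion(eid):
                continue
            presence[arm_id].add(eid)
            if far:
                builder.sentence(
                    [
                        "Participants received ",
                        ("entity", eid, phrase, None, arm_id),
                        " .",
                    ]
                )
            else:
                builder.sentence(
                    [
                        "The ",
                        ("arm", arm_surface(i)),
                        " received ",
                        ("entity", eid, phrase, None, arm_id),
                        " .",
                    ]
                )
        for eid, (prefix, unit, low, high, dec) in ARM_VALUE_TEMPLATES.items():
            if rng.random() >= config.inclusion(eid, 1.0):
                continue
            value = float(_fmt(rng.uniform(low, high), dec))
            arm_numeric[arm_id][eid] = value
            if eid in config.table_only_entities:
                table_rows[arm_id][eid] = _fmt(value, dec)
                continue
            surface = f"{_fmt(value, dec)} {unit}"
            if far:
                builder.sentence(
                    [
                        "This condition",
                        prefix,
                        ("entity", eid, surface, value, arm_id),
                        " .",
                    ]
                )
            else:
                builder.sentence(
                    [
                        "The ",
                        ("arm", arm_surface(i)),
                        prefix,
                        ("entity", eid, surface, value, arm_id),
                        " .",
                    ]
                )

    # outcomes from the linear model, using the values as rendered
    linear_pred: dict[str, float] = {}
    outcomes: dict[str, float] = {}
    for arm_id in arm_ids:
        pred = config.intercept
        for eid, beta in config.presence_effects.items():
            if eid in presence[arm_id]:
                pred += beta
        for eid, gamma in config.numeric_effects.items():
            value = arm_numeric[arm_id].get(eid, numeric_values.get(eid))
            if value is not None:
                pred += gamma * value
        linear_pred[arm_id] = pred
        noisy = pred + rng.normal(0.0, config.noise_sd) if config.noise_sd else pred
        outcomes[arm_id] = float(_fmt(min(100.0, max(0.0, noisy)), 1))

    for i, arm_id in enumerate(arm_ids):
        value = outcomes[arm_id]
        surface = f"{value:.1f} percent"
        if far:
            builder.sentence(
                [
                    "Abstinence at twelve months was ",
                    ("entity", config.outcome_entity, surface, value, arm_id),
                    " .",
                ]
            )
        else:
            builder.sentence(
                [
                    "In the ",
                    ("arm", arm_surface(i)),
                    " , ",
                    ("entity", config.outcome_entity, surface, value, arm_id),
                    " achieved abstinence at twelve months .",
                ]
            )

    # optional results table
    tables: list[Table] = []
    annotations_from_table: list[Annotation] = []
    emit_table = (
        config.table_entities
        and rng.random() < config.table_probability
        and any(
            eid in arm_numeric[a]
            for a in arm_ids
            for eid in config.table_entities
        )
    )
    if emit_table:
        cols = [
            eid for eid in config.table_entities
            if any(eid in arm_numeric[a] for a in arm_ids)
        ]
        header = [""] + [eid.replace("_", " ") for eid in cols]
        cells = [header]
        for i, arm_id in enumerate(arm_ids):
            row = [lexicon[i][0]]
            for eid in cols:
                value = arm_numeric[arm_id].get(eid)
                cell = "" if value is None else _fmt(value, 0 if value == int(value) else 1)
                row.append(cell)
                if cell:
                    annotations_from_table.append(
                        Annotation(
                            doc_id=doc_id,
                            entity_id=eid,
                            span=None,
                            raw_text=cell,
                            context_text="",
                            value=float(cell),
                            arm_ref=arm_id,
                        )
                    )
            cells.append(row)
        tables.append(
            Table(
                table_id=f"{doc_id}_t1",
                caption="Treatment characteristics by study group",
                cells=cells,
            )
        )

    document = build_document(doc_id, builder.text, tables)

    # gold arms: canonical label plus every surface mention with its span
    arms = []
    for i, arm_id in enumerate(arm_ids):
        synonyms = set(lexicon[i])
        mentions = [
            ArmMention(surface=s, span=span)
            for s, span in builder.arm_mentions
            if s in synonyms
        ]
        arms.append(Arm(arm_id=arm_id, label=lexicon[i][0], mentions=mentions))

    annotations = [
        Annotation(
            doc_id=doc_id,
            entity_id=eid,
            span=span,
            raw_text=surface,
            context_text=context,
            value=value,
            arm_ref=arm_ref,
        )
        for eid, span, surface, value, arm_ref, context in builder.annotations
    ] + annotations_from_table

    study = AnnotatedStudy(
        doc_id=doc_id,
        text=builder.text,
        arms=arms,
        annotations=annotations,
        outcomes=[
            OutcomeRecord(
                arm_id=a, entity_id=config.outcome_entity, value=outcomes[a]
            )
            for a in arm_ids
        ],
    )
    study.validate()
    return GoldStudy(
        study=study, document=document, linear_pred=linear_pred, tables=tables
    )


def generate_corpus(config: GeneratorConfig) -> list[GoldStudy]:
    """Generate ``config.n_docs`` studies with per-study derived seeds."""
    if config.n_docs < 1:
        raise ValidationError("n_docs must be >= 1")
    return [generate_study(config, i) for i in range(config.n_docs)]


def entity_frequencies(corpus: list[GoldStudy]) -> dict[str, int]:
    """Documents containing at least one annotation per entity (sparsity check)."""
    freqs: dict[str, int] = {}
    for gold in corpus:
        for eid in {a.entity_id for a in gold.study.annotations}:
            freqs[eid] = freqs.get(eid, 0) + 1
    return freqs


def corrupt_annotations(
    studies: list[AnnotatedStudy],
    drop_rate: float = 0.0,
    relabel_rate: float = 0.0,
    value_noise_rate: float = 0.0,
    seed: int = 0,
) -> list[AnnotatedStudy]:
    """Degrade gold annotations to emulate an imperfect annotator.

    Deterministic given the seed: drops whole annotations, swaps entity
    labels within the set of labels seen in the corpus (respecting
    value/presence compatibility), and perturbs values by +/-10%.
    """
    for rate in (drop_rate, relabel_rate, value_noise_rate):
        if not 0 <= rate <= 1:
            raise ValidationError("corruption rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    value_labels = sorted(
        {
            a.entity_id
            for s in studies
            for a in s.annotations
            if a.value is not None
        }
    )
    presence_labels = sorted(
        {
            a.entity_id
            for s in studies
            for a in s.annotations
            if a.value is None
        }
    )
    out = []
    for study in studies:
        kept: list[Annotation] = []
        for ann in study.annotations:
            if rng.random() < drop_rate:
                continue
            entity_id = ann.entity_id
            value = ann.value
            if rng.random() < relabel_rate:
                pool = value_labels if ann.value is not None else presence_labels
                alternatives = [e for e in pool if e != entity_id]
                if alternatives:
                    entity_id = alternatives[int(rng.integers(len(alternatives)))]
            if value is not None and rng.random() < value_noise_rate:
                value = round(value * (1.0 + rng.uniform(-0.1, 0.1)), 2)
            kept.append(
                Annotation(
                    doc_id=ann.doc_id,
                    entity_id=entity_id,
                    span=ann.span,
                    raw_text=ann.raw_text,
                    context_text=ann.context_text,
                    value=value,
                    arm_ref=ann.arm_ref,
                )
            )
        out.append(replace(study, annotations=kept))
    return out


# ---------------------------------------------------------------------------
# ready-made configurations for experiments


def default_signal_config(seed: int = 0, n_docs: int = 50) -> GeneratorConfig:
    """Moderate additive signal; clean near-window arm mentions."""
    return GeneratorConfig(
        seed=seed,
        n_docs=n_docs,
        presence_effects={
            "bct_goal_setting": 6.0,
            "drug_nrt": 8.0,
            "delivery_group": -4.0,
            "bct_social_support": 3.0,
        },
        numeric_effects={"mean_age": -0.2, "sessions_count": 0.8},
        noise_sd=5.0,
    )


def zero_signal_config(seed: int = 0, n_docs: int = 40) -> GeneratorConfig:
    """Outcomes are intercept + noise only: nothing to learn."""
    return GeneratorConfig(
        seed=seed,
        n_docs=n_docs,
        intercept=25.0,
        presence_effects={},
        numeric_effects={},
        noise_sd=8.0,
    )


def strong_signal_config(seed: int = 0, n_docs: int = 150) -> GeneratorConfig:
    """Additive model explaining roughly 80% of outcome variance.

    Signal variance (analytic, inclusion probability 0.5 per presence
    entity, uniform numeric ranges) is ~61; noise_sd is chosen so that
    R^2 = signal / (signal + noise^2) is about 0.8.
    """
    presence_effects = {
        "bct_goal_setting": 7.0,
        "drug_nrt": 9.0,
        "bct_problem_solving": -6.0,
        "delivery_phone": 5.0,
    }
    numeric_effects = {"mean_age": -0.25, "sessions_count": 1.0}
    signal_var = sum(b**2 * 0.25 for b in presence_effects.values())
    signal_var += numeric_effects["mean_age"] ** 2 * (60 - 30) ** 2 / 12
    signal_var += numeric_effects["sessions_count"] ** 2 * (12 - 4) ** 2 / 12
    noise_sd = float(np.sqrt(signal_var * (1 - 0.8) / 0.8))
    return GeneratorConfig(
        seed=seed,
        n_docs=n_docs,
        intercept=40.0,
        presence_effects=presence_effects,
        numeric_effects=numeric_effects,
        noise_sd=noise_sd,
    )
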