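"""BIO sequence labelling: encode/decode, gazetteer and statistical taggers.

Two model families sit behind one interface (``model.tag(sentence) ->
TagSequence``):

* ``gazetteer`` — a deterministic longest-match dictionary built from
  training mentions (leftmost-longest tie-break);
* ``statistical`` — a multinomial logistic model over windowed token
  features, decoded with a Viterbi pass whose transition constraints force
  BIO-valid output (the role a CRF layer plays in neural taggers).
  Locally trained skip-gram word vectors, or externally supplied vectors,
  can be concatenated to the discrete features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .embeddings import train_skipgram
from .errors import AlignmentError, TrainingError, ValidationError
from .ingest import Document
from .schema import ARM_NAME

_TOKEN_RE = re.compile(r"\d+\.\d+|\w+|[^\w\s]")

Token = tuple[str, int, int]


def tokenize(text: str) -> list[Token]:
    """Whitespace/punctuation tokenization with character offsets.

    Decimal numerals ("44.5") are kept as single tokens.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass
class Mention:
    """A labelled span in a sentence or pseudo-sentence."""

    label: str
    start: int
    end: int
    text: str = ""
    source: str = "body"  # "body" | "table"
    context_id: str = "body"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"mention span empty: {self.start}..{self.end}")


@dataclass
class TagSequence:
    tokens: list[Token]
    tags: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValidationError("tags and tokens differ in length")

    def is_valid(self) -> bool:
        prev = "O"
        for tag in self.tags:
            if tag.startswith("I-"):
                label = tag[2:]
                if prev not in (f"B-{label}", f"I-{label}"):
                    return False
            prev = tag
        return True


@dataclass
class TaggerConfig:
    family: str = "statistical"  # "gazetteer" | "statistical"
    seed: int = 0
    epochs: int = 1
    embedding_dim: int = 0  # 0 disables locally trained skip-gram features
    embedding_window: int = 2
    external_vectors: Mapping[str, np.ndarray] | None = None
    regularization_c: float = 10.0

    def __post_init__(self) -> None:
        if self.family not in ("gazetteer", "statistical"):
            raise ValidationError(f"unknown model family {self.family!r}")
        if self.embedding_dim < 0:
            raise ValidationError("embedding_dim must be >= 0")


# ---------------------------------------------------------------------------
# BIO encoding / decoding


def encode_bio(
    tokens: Sequence[Token], mentions: Sequence[Mention]
) -> TagSequence:
    """Convert char-span mentions into BIO tags over ``tokens``.

    Mentions must align exactly with token boundaries and must not overlap.
    Adjacent same-label mentions stay separate (B-X B-X, never B-X I-X).
    """
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise AlignmentError(
                f"overlapping mentions at {a.start}..{a.end} and {b.start}..{b.end}"
            )
    starts = {tok[1]: i for i, tok in enumerate(tokens)}
    ends = {tok[2]: i for i, tok in enumerate(tokens)}
    tags = ["O"] * len(tokens)
    for m in ordered:
        if m.start not in starts or m.end not in ends:
            raise AlignmentError(
                f"mention {m.start}..{m.end} crosses a token boundary"
            )
        first, last = starts[m.start], ends[m.end]
        tags[first] = f"B-{m.label}"
        for i in range(first + 1, last + 1):
            tags[i] = f"I-{m.label}"
    return TagSequence(tokens=list(tokens), tags=tags)


def decode_bio(sequence: TagSequence) -> list[Mention]:
    """Recover mentions from a tag sequence (inverse of :func:`encode_bio`).

    Invalid sequences are repaired leniently: a leading I-X (after O or a
    different label) is promoted to B-X.
    """
    def surface_for(start: int, end: int) -> str:
        parts: list[str] = []
        prev_end: int | None = None
        for s, ts, te in sequence.tokens:
            if ts >= start and te <= end:
                if prev_end is not None:
                    parts.append(" " * (ts - prev_end))
                parts.append(s)
                prev_end = te
        return "".join(parts)

    mentions: list[Mention] = []
    current: tuple[str, int, int] | None = None  # label, start, end
    for tok, tag in zip(sequence.tokens, sequence.tags):
        surface, start, end = tok
        if tag == "O":
            if current:
                mentions.append(Mention(*current, surface_for(*current[1:])))
            current = None
        elif tag.startswith("B-"):
            if current:
                mentions.append(Mention(*current, surface_for(*current[1:])))
            current = (tag[2:], start, end)
        else:  # I-
            label = tag[2:]
            if current and current[0] == label:
                current = (label, current[1], end)
            else:  # repair: treat as B-
                if current:
                    mentions.append(Mention(*current, surface_for(*current[1:])))
                current = (label, start, end)
    if current:
        mentions.append(Mention(*current, surface_for(*current[1:])))
    return mentions


# ---------------------------------------------------------------------------
# gazetteer tagger


class GazetteerTagger:
    """Longest-match dictionary tagger built from training mentions."""

    family = "gazetteer"

    def __init__(self, config: TaggerConfig):
        self.config = config
        # normalized token tuple -> {label: count}
        self._entries: dict[tuple[str, ...], dict[str, int]] = {}
        self._max_len = 0

    @staticmethod
    def _norm(surfaces: Iterable[str]) -> tuple[str, ...]:
        return tuple(s.lower() for s in surfaces)

    def fit(self, corpus: Sequence[TagSequence]) -> "GazetteerTagger":
        for seq in corpus:
            for m in decode_bio(seq):
                toks = [t for t in seq.tokens if m.start <= t[1] and t[2] <= m.end]
                key = self._norm(s for s, _, _ in toks)
                if not key:
                    continue
                labels = self._entries.setdefault(key, {})
                labels[m.label] = labels.get(m.label, 0) + 1
                self._max_len = max(self._max_len, len(key))
        return self

    def _label_for(self, key: tuple[str, ...]) -> str | None:
        labels = self._entries.get(key)
        if not labels:
            return None
        return max(labels.items(), key=lambda kv: kv[1])[0]

    def tag(self, text: str) -> TagSequence:
        tokens = tokenize(text)
        surfaces = self._norm(s for s, _, _ in tokens)
        tags = ["O"] * len(tokens)
        i = 0
        while i < len(tokens):
            matched = 0
            label = None
            limit = min(self._max_len, len(tokens) - i)
            for length in range(limit, 0, -1):  # leftmost-longest wins
                cand = self._label_for(surfaces[i : i + length])
                if cand is not None:
                    matched, label = length, cand
                    break
            if matched:
                tags[i] = f"B-{label}"
                for j in range(i + 1, i + matched):
                    tags[j] = f"I-{label}"
                i += matched
            else:
                i += 1
        return TagSequence(tokens=tokens, tags=tags)


# ---------------------------------------------------------------------------
# statistical tagger


def _shape(word: str) -> str:
    out = []
    for ch in word:
        if ch.isdigit():
            out.append("d")
        elif ch.isalpha():
            out.append("X" if ch.isupper() else "x")
        else:
            out.append(ch)
    shape = "".join(out)
    return re.sub(r"(.)\1{2,}", r"\1\1", shape)


def _token_features(surfaces: list[str], i: int) -> dict[str, float]:
    w = surfaces[i]
    lw = w.lower()
    feats: dict[str, float] = {
        f"w={lw}": 1.0,
        f"shape={_shape(w)}": 1.0,
        f"suf3={lw[-3:]}": 1.0,
        f"pre2={lw[:2]}": 1.0,
    }
    if re.fullmatch(r"\d+(\.\d+)?", w):
        feats["is_num"] = 1.0
    for off in (-2, -1, 1, 2):
        j = i + off
        if 0 <= j < len(surfaces):
            feats[f"w[{off}]={surfaces[j].lower()}"] = 1.0
        else:
            feats[f"pad[{off}]"] = 1.0
    return feats


class StatisticalTagger:
    """Feature-based sequence labeller with BIO-constrained Viterbi decoding."""

    family = "statistical"

    def __init__(self, config: TaggerConfig):
        self.config = config
        self._vectorizer: DictVectorizer | None = None
        self._clf: LogisticRegression | None = None
        self._classes: list[str] = []
        self._word_vectors: dict[str, np.ndarray] = {}

    def _featurize(self, surfaces: list[str]) -> list[dict[str, float]]:
        rows = []
        for i in range(len(surfaces)):
            feats = _token_features(surfaces, i)
            vec = self._word_vectors.get(surfaces[i].lower())
            if vec is not None:
                for j, x in enumerate(vec):
                    feats[f"emb{j}"] = float(x)
            ext = self.config.external_vectors
            if ext is not None:
                evec = ext.get(surfaces[i].lower())
                if evec is not None:
                    for j, x in enumerate(evec):
                        feats[f"ext{j}"] = float(x)
            rows.append(feats)
        return rows

    def fit(self, corpus: Sequence[TagSequence]) -> "StatisticalTagger":
        if self.config.embedding_dim > 0:
            sentences = [
                [s.lower() for s, _, _ in seq.tokens] for seq in corpus
            ]
            self._word_vectors = train_skipgram(
                sentences,
                dim=self.config.embedding_dim,
                window=self.config.embedding_window,
                seed=self.config.seed,
            )
        X_rows: list[dict[str, float]] = []
        y: list[str] = []
        for seq in corpus:
            surfaces = [s for s, _, _ in seq.tokens]
            X_rows.extend(self._featurize(surfaces))
            y.extend(seq.tags)
        if not X_rows:
            raise TrainingError("no tokens in training corpus")
        self._vectorizer = DictVectorizer()
        X = self._vectorizer.fit_transform(X_rows)
        self._clf = LogisticRegression(
            C=self.config.regularization_c,
            max_iter=200 * max(1, self.config.epochs),
            random_state=self.config.seed,
        )
        self._clf.fit(X, y)
        self._classes = list(self._clf.classes_)
        return self

    def _transition_ok(self, prev: str, cur: str) -> bool:
        if not cur.startswith("I-"):
            return True
        label = cur[2:]
        return prev in (f"B-{label}", f"I-{label}")

    def tag(self, text: str) -> TagSequence:
        if self._clf is None or self._vectorizer is None:
            raise TrainingError("tagger is not trained")
        tokens = tokenize(text)
        if not tokens:
            return TagSequence(tokens=[], tags=[])
        surfaces = [s for s, _, _ in tokens]
        X = self._vectorizer.transform(self._featurize(surfaces))
        log_probs = self._clf.predict_log_proba(X)
        tags = self._viterbi(log_probs)
        return TagSequence(tokens=tokens, tags=tags)

    def _viterbi(self, log_probs: np.ndarray) -> list[str]:
        n, k = log_probs.shape
        classes = self._classes
        neg_inf = -1e18
        score = np.array(
            [
                log_probs[0, j] if self._transition_ok("O", classes[j]) else neg_inf
                for j in range(k)
            ]
        )
        back = np.zeros((n, k), dtype=int)
        allowed = np.array(
            [
                [self._transition_ok(classes[p], classes[c]) for c in range(k)]
                for p in range(k)
            ]
        )
        trans = np.where(allowed, 0.0, neg_inf)
        for t in range(1, n):
            cand = score[:, None] + trans
            back[t] = np.argmax(cand, axis=0)
            score = cand[back[t], np.arange(k)] + log_probs[t]
        path = [int(np.argmax(score))]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [classes[j] for j in path]


# ---------------------------------------------------------------------------
# training / application / persistence


def train_tagger(
    corpus: Sequence[TagSequence],
    config: TaggerConfig,
    allowed_labels: Iterable[str] | None = None,
) -> GazetteerTagger | StatisticalTagger:
    """Fit a tagger of the configured family on BIO-tagged sentences."""
    if not corpus:
        raise TrainingError("training corpus is empty")
    if allowed_labels is not None:
        allowed = set(allowed_labels) | {ARM_NAME}
        for seq in corpus:
            for tag in seq.tags:
                if tag != "O" and tag[2:] not in allowed:
                    raise ValidationError(f"unknown label in corpus: {tag[2:]!r}")
    model: GazetteerTagger | StatisticalTagger
    if config.family == "gazetteer":
        model = GazetteerTagger(config)
    else:
        model = StatisticalTagger(config)
    return model.fit(corpus)


def tag_document(
    model: GazetteerTagger | StatisticalTagger, document: Document
) -> list[Mention]:
    """Tag body sentences and table pseudo-sentences of a document.

    Body mentions carry document-level character offsets; table mentions
    keep offsets local to their pseudo-sentence and record its identity in
    ``context_id``.  Output is sorted by (source, span start), body first.
    """
    mentions: list[Mention] = []
    for start, end in document.sentences:
        seq = model.tag(document.body_text[start:end])
        for m in decode_bio(seq):
            mentions.append(
                Mention(
                    label=m.label,
                    start=m.start + start,
                    end=m.end + start,
                    text=document.body_text[m.start + start : m.end + start],
                    source="body",
                    context_id="body",
                )
            )
    for idx, ps in enumerate(document.pseudo_sentences):
        seq = model.tag(ps.text)
        for m in decode_bio(seq):
            mentions.append(
                Mention(
                    label=m.label,
                    start=m.start,
                    end=m.end,
                    text=ps.text[m.start : m.end],
                    source="table",
                    context_id=f"table:{ps.table_id}:{idx}",
                )
            )
    mentions.sort(key=lambda m: (m.source, m.context_id, m.start))
    return mentions


def save_model(
    model: GazetteerTagger | StatisticalTagger, path: str
) -> None:
    """Serialize a trained tagger (config and seed embedded) to one file."""
    joblib.dump({"family": model.family, "model": model}, path)


def load_model(path: str) -> GazetteerTagger | StatisticalTagger:
    payload = joblib.load(path)
    return payload["model"]
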