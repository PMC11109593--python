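"""Study-arm machinery: arm-count detection, complete-link clustering of
arm-name mentions, cluster labelling, and proximity-based association of
entity mentions to arms.

The number of arms n is read off the stereotyped phrasing "randomised
into/in n groups/arms/conditions" when present; otherwise clustering runs
until the best complete-link similarity drops below a configurable floor.
Entities are linked to the arm of the nearest arm-name mention within a
token window t, falling back to the whole study.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ClusteringError, ValidationError
from .ingest import Document
from .schema import WHOLE_STUDY, Arm, ArmMention
from .tagging import Mention, tokenize

_WORD_NUMERALS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
}

_ARM_COUNT_RE = re.compile(
    r"\b(?:into|in)\s+(\d+|" + "|".join(_WORD_NUMERALS) + r")\s+"
    r"(?:groups|arms|conditions)\b",
    re.IGNORECASE,
)

_PUNCT_RE = re.compile(r"[^\w\s]")


@dataclass
class ArmResolutionConfig:
    window: int = 30  # t, in tokens; set empirically, CLI-exposed
    tie_break: str = "prefer_preceding"
    similarity_floor: float = 0.2  # fallback clustering stop when n unknown

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValidationError("window must be >= 0")
        if self.tie_break not in ("prefer_preceding", "prefer_following"):
            raise ValidationError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class ArmAssignment:
    mention_index: int
    target: str  # arm_id or WHOLE_STUDY
    distance: int | None = None


def detect_arm_count(text: str) -> int | None:
    """Return n from the first "into/in n groups" pattern, else None."""
    match = _ARM_COUNT_RE.search(text)
    if match is None:
        return None
    numeral = match.group(1).lower()
    if numeral.isdigit():
        return int(numeral)
    return _WORD_NUMERALS[numeral]


def _norm_tokens(surface: str) -> frozenset[str]:
    return frozenset(_PUNCT_RE.sub(" ", surface.lower()).split())


def mention_similarity(a: str, b: str) -> float:
    """Token-set Jaccard similarity on lowercased, punctuation-free tokens."""
    if not a.strip() or not b.strip():
        raise ValidationError("mention surfaces must be non-empty")
    ta, tb = _norm_tokens(a), _norm_tokens(b)
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


def label_cluster(members: dict[str, tuple[int, int]]) -> str:
    """Pick the cluster label: highest count, ties by earliest occurrence.

    ``members`` maps surface form -> (count, first occurrence offset).
    """
    if not members:
        raise ClusteringError("empty cluster")
    return min(members.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))[0]


def complete_link_clusters(
    keys: list[str],
    similarity,
    n: int | None,
    floor: float | None = None,
) -> list[list[str]]:
    """Greedy complete-link agglomeration over ``keys``.

    Repeatedly merges the pair of clusters whose complete-link similarity
    (the similarity of their two most dissimilar members) is highest,
    stopping at ``n`` clusters, or — with ``n`` None — once the best merge
    similarity drops below ``floor``.  Merge ties are broken towards the
    lexicographically smallest cluster pair for reproducibility.
    """
    sim_cache = {
        (a, b): similarity(a, b)
        for i, a in enumerate(keys)
        for b in keys[i + 1 :]
    }

    def pair_sim(a: str, b: str) -> float:
        if a == b:
            return 1.0
        return sim_cache[(a, b)] if (a, b) in sim_cache else sim_cache[(b, a)]

    clusters: list[list[str]] = [[k] for k in keys]
    target = n if n is not None else 1
    while len(clusters) > target:
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        best_pair: tuple[int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                s = min(
                    pair_sim(a, b) for a in clusters[i] for b in clusters[j]
                )
                ka = tuple(sorted(clusters[i]))
                kb = tuple(sorted(clusters[j]))
                if best is None or s > best[0] or (
                    s == best[0]
                    and tuple(sorted([ka, kb])) < tuple(sorted([best[1], best[2]]))
                ):
                    best = (s, ka, kb)
                    best_pair = (i, j)
        assert best is not None and best_pair is not None
        if n is None and floor is not None and best[0] < floor:
            break
        i, j = best_pair
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


def cluster_arm_mentions(
    mentions: list[Mention],
    n: int | None,
    config: ArmResolutionConfig | None = None,
) -> list[Arm]:
    """Complete-link agglomerative clustering of arm-name mentions.

    Cluster similarity is that of the two most dissimilar members.  Merging
    stops at ``n`` clusters, or — when ``n`` is None — once the best
    complete-link similarity falls below ``config.similarity_floor``.  Each
    cluster becomes an :class:`Arm` labelled by its most frequent surface
    form.
    """
    config = config or ArmResolutionConfig()
    if not mentions:
        raise ClusteringError("no arm mentions to cluster")

    # distinct surface forms with counts and first occurrence
    stats: dict[str, tuple[int, int]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for order, m in enumerate(mentions):
        pos = m.start if m.source == "body" else 10**9 + order
        count, first = stats.get(m.text, (0, pos))
        stats[m.text] = (count + 1, min(first, pos))
        spans.setdefault(m.text, []).append((m.start, m.end))

    surfaces = sorted(stats, key=lambda s: (stats[s][1], s))
    if n is not None and n > len(surfaces):
        raise ClusteringError(
            f"requested {n} arms but only {len(surfaces)} distinct mentions"
        )

    clusters = complete_link_clusters(
        surfaces,
        mention_similarity,
        n=n,
        floor=config.similarity_floor if n is None else None,
    )
    clusters.sort(key=lambda c: min(stats[s][1] for s in c))
    arms = []
    for k, members in enumerate(clusters, start=1):
        label = label_cluster({s: stats[s] for s in members})
        arms.append(
            Arm(
                arm_id=f"arm_{k}",
                label=label,
                mentions=[
                    ArmMention(surface=s, span=spans[s][0]) for s in sorted(
                        members, key=lambda s: (stats[s][1], s)
                    )
                ],
            )
        )
    return arms


def _mention_token_range(
    m: Mention, boundaries: list[tuple[int, int]]
) -> tuple[int, int]:
    """Token-index range [first, last] covered by a char-span mention."""
    first = last = None
    for i, (ts, te) in enumerate(boundaries):
        if te > m.start and ts < m.end:
            if first is None:
                first = i
            last = i
    if first is None:  # mention between tokens; snap to nearest
        first = last = sum(1 for ts, _ in boundaries if ts < m.start)
        first = last = min(first, len(boundaries) - 1)
    return first, last


def associate_entities(
    document: Document,
    entity_mentions: list[Mention],
    arm_mentions: list[Mention],
    arms: list[Arm],
    config: ArmResolutionConfig | None = None,
) -> list[ArmAssignment]:
    """Assign each entity mention to the arm of the nearest arm-name mention.

    Distances are measured in tokens between nearest token boundaries; a
    mention farther than ``config.window`` from every arm mention is
    assigned to the whole study.  Table (pseudo-sentence) mentions only see
    arm mentions inside the same pseudo-sentence.
    """
    config = config or ArmResolutionConfig()
    surface_to_arm: dict[str, str] = {}
    for arm in arms:
        for am in arm.mentions:
            surface_to_arm.setdefault(am.surface, arm.arm_id)

    # token boundaries per context (body text or one pseudo-sentence)
    texts = {"body": document.body_text}
    for idx, ps in enumerate(document.pseudo_sentences):
        texts[f"table:{ps.table_id}:{idx}"] = ps.text
    boundaries = {
        ctx: [(s, e) for _, s, e in tokenize(text)] for ctx, text in texts.items()
    }

    arm_positions: dict[str, list[tuple[int, int, str]]] = {}
    for am in arm_mentions:
        arm_id = surface_to_arm.get(am.text)
        if arm_id is None or am.context_id not in boundaries:
            continue
        first, last = _mention_token_range(am, boundaries[am.context_id])
        arm_positions.setdefault(am.context_id, []).append((first, last, arm_id))

    prefer_preceding = config.tie_break == "prefer_preceding"
    assignments = []
    for idx, em in enumerate(entity_mentions):
        ctx = em.context_id if em.context_id in boundaries else "body"
        candidates = arm_positions.get(ctx, [])
        if not candidates:
            assignments.append(ArmAssignment(idx, WHOLE_STUDY))
            continue
        e_first, e_last = _mention_token_range(em, boundaries[ctx])
        best = None
        for a_first, a_last, arm_id in candidates:
            if a_last < e_first:
                dist, side = e_first - a_last - 1, 0  # preceding
            elif a_first > e_last:
                dist, side = a_first - e_last - 1, 1  # following
            else:
                dist, side = 0, 0
            if not prefer_preceding:
                side = 1 - side
            key = (dist, side, a_first)
            if best is None or key < best[0]:
                best = (key, arm_id, dist)
        assert best is not None
        _, arm_id, dist = best
        if dist <= config.window:
            assignments.append(ArmAssignment(idx, arm_id, dist))
        else:
            assignments.append(ArmAssignment(idx, WHOLE_STUDY))
    return assignments
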