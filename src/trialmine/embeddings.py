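"""Skip-gram embeddings with negative sampling (numpy implementation).

Used in two places: word vectors trained on corpus sentences, and node
vectors trained on random-walk sequences over the annotation co-occurrence
graph.  Deliberately small-scale and fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError


def train_skipgram(
    sentences: list[list[str]],
    dim: int = 16,
    window: int = 2,
    epochs: int = 3,
    negative: int = 5,
    learning_rate: float = 0.05,
    min_count: int = 1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Learn one vector per token type by predicting context tokens.

    Returns a mapping ``token -> vector`` of length ``dim``.  Training is a
    plain SGD loop over (center, context) pairs with ``negative`` sampled
    negatives per pair; the unigram distribution is raised to 3/4 for
    negative sampling.
    """
    if dim <= 0 or window <= 0 or epochs <= 0:
        raise TrainingError("dim, window and epochs must be positive")
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(
        (w for w, c in counts.items() if c >= min_count),
        key=lambda w: (-counts[w], w),
    )
    if not vocab:
        raise TrainingError("empty vocabulary")
    index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    neg_probs = freq / freq.sum()

    # precompute training pairs once; order is deterministic
    centers: list[int] = []
    contexts: list[int] = []
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        for i, c in enumerate(ids):
            lo = max(0, i - window)
            hi = min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers:
        raise TrainingError("no training pairs (sentences too short)")
    centers_arr = np.array(centers)
    contexts_arr = np.array(contexts)
    n_pairs = len(centers_arr)

    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        negs = rng.choice(V, size=(n_pairs, negative), p=neg_probs)
        for k, idx in enumerate(order):
            c = centers_arr[idx]
            targets = np.concatenate(([contexts_arr[idx]], negs[k]))
            labels = np.zeros(negative + 1)
            labels[0] = 1.0
            v = W_in[c]
            scores = W_out[targets] @ v
            preds = 1.0 / (1.0 + np.exp(-np.clip(scores, -30, 30)))
            grad = (preds - labels) * learning_rate
            W_in[c] = v - grad @ W_out[targets]
            W_out[targets] -= np.outer(grad, v)

    return {w: W_in[i].copy() for i, w in enumerate(vocab)}


def mean_pool(
    tokens: list[str], vectors: dict[str, np.ndarray], dim: int
) -> np.ndarray:
    """Average the vectors of known tokens; zeros if none are known."""
    known = [vectors[t] for t in tokens if t in vectors]
    if not known:
        return np.zeros(dim)
    return np.mean(known, axis=0)
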