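"""Unsupervised statistical keyword extraction.

Implements the YAKE family of within-text features: no external corpus, no
training.  Every unique term receives a relevance score built from

* casing — how often the term appears as an acronym or capitalized mid-sentence,
* position — (log-damped) median index of the sentences it first appears in,
* frequency — term frequency normalized by the mean and standard deviation of
  all term frequencies,
* relatedness to context — diversity of the distinct terms co-occurring in a
  one-token window on each side, which penalizes stopword-like terms,
* dispersion — fraction of sentences containing the term.

Candidate keywords are contiguous n-grams (no stopwords, no pure numbers)
scored by combining their terms' scores; *lower scores mean more relevant*.
Near-duplicate candidates are suppressed with a Levenshtein-ratio filter.

A plain frequency-rank extractor is available as well (``extractor="frequency"``),
for users who read "most common keywords" literally; the statistical scorer is
the default.
"""

from __future__ import annotations

import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass

from .textprep import STOPWORDS

_SENT_SPLIT_RE = re.compile(r"[.!?\n]+")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class TermStats:
    """Per-term feature scores; ``score`` is the combined relevance (lower = better)."""

    term: str
    tf: float
    casing: float
    position: float
    frequency: float
    relatedness: float
    dispersion: float
    score: float


def split_sentences(text: str) -> list[list[str]]:
    """Split into sentences of surface-form tokens (case preserved)."""
    sentences = []
    for raw in _SENT_SPLIT_RE.split(text):
        toks = _TOKEN_RE.findall(raw)
        if toks:
            sentences.append(toks)
    return sentences


def _is_acronym(tok: str) -> bool:
    return len(tok) > 1 and tok.isupper()


def _is_capitalized(tok: str) -> bool:
    return tok[0].isupper() and not tok.isupper() and tok[1:].islower()


def term_statistics(sentences: list[list[str]],
                    stopwords: frozenset[str] = STOPWORDS,
                    window: int = 1) -> dict[str, TermStats]:
    """Compute the per-term statistical features over tokenized sentences."""
    tf: Counter[str] = Counter()
    tf_upper: Counter[str] = Counter()
    tf_cap: Counter[str] = Counter()
    sent_ids: dict[str, list[int]] = defaultdict(list)
    left: dict[str, Counter[str]] = defaultdict(Counter)
    right: dict[str, Counter[str]] = defaultdict(Counter)

    for s_idx, sent in enumerate(sentences):
        lower = [t.lower() for t in sent]
        for pos, tok in enumerate(sent):
            term = lower[pos]
            tf[term] += 1
            if _is_acronym(tok):
                tf_upper[term] += 1
            if pos > 0 and _is_capitalized(tok):
                tf_cap[term] += 1
            sent_ids[term].append(s_idx)
            for off in range(1, window + 1):
                if pos - off >= 0:
                    left[term][lower[pos - off]] += 1
                if pos + off < len(lower):
                    right[term][lower[pos + off]] += 1

    valid_tfs = [f for t, f in tf.items() if t not in stopwords and not t.isdigit()]
    mean_tf = sum(valid_tfs) / len(valid_tfs) if valid_tfs else 0.0
    if len(valid_tfs) > 1:
        var = sum((f - mean_tf) ** 2 for f in valid_tfs) / (len(valid_tfs) - 1)
        std_tf = math.sqrt(var)
    else:
        std_tf = 0.0
    max_tf = max(tf.values()) if tf else 1
    n_sent = max(len(sentences), 1)

    stats: dict[str, TermStats] = {}
    for term, freq in tf.items():
        casing = max(tf_upper[term], tf_cap[term]) / (1.0 + math.log(freq))
        ids = sorted(sent_ids[term])
        median_sent = ids[len(ids) // 2] if len(ids) % 2 else (
            (ids[len(ids) // 2 - 1] + ids[len(ids) // 2]) / 2.0)
        position = math.log(math.log(3.0 + median_sent))
        frequency = freq / (mean_tf + std_tf) if (mean_tf + std_tf) > 0 else 0.0
        dl = len(left[term]) / sum(left[term].values()) if left[term] else 0.0
        dr = len(right[term]) / sum(right[term].values()) if right[term] else 0.0
        relatedness = 1.0 + (dl + dr) * (freq / max_tf)
        dispersion = len(set(ids)) / n_sent
        score = (relatedness * position) / (
            casing + frequency / relatedness + dispersion / relatedness)
        stats[term] = TermStats(term, freq, casing, position, frequency,
                                relatedness, dispersion, score)
    return stats


def _candidates(sentences: list[list[str]], ngram_max: int,
                stopwords: frozenset[str]) -> Counter[tuple[str, ...]]:
    """Contiguous n-grams with no stopword and no pure number, with counts."""
    counts: Counter[tuple[str, ...]] = Counter()
    for sent in sentences:
        lower = [t.lower() for t in sent]
        ok = [t not in stopwords and not t.isdigit() for t in lower]
        for i in range(len(lower)):
            for n in range(1, ngram_max + 1):
                if i + n > len(lower):
                    break
                if not all(ok[i:i + n]):
                    break
                counts[tuple(lower[i:i + n])] += 1
    return counts


def levenshtein_ratio(a: str, b: str) -> float:
    """Similarity in [0,1]: 1 − edit distance / max length."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return 1.0 - prev[-1] / max(len(a), len(b))


def rank_keywords(text: str, max_k: int, ngram_max: int = 3, *,
                  extractor: str = "yake",
                  stopwords: frozenset[str] = STOPWORDS,
                  window: int = 1,
                  dedup_threshold: float = 0.9) -> list[tuple[str, float]]:
    """Rank candidate keywords of ``text``; return up to ``max_k`` (keyword, score).

    Lower score = more relevant; the result is sorted ascending with
    lexicographic tie-break on the keyword string for determinism.  With
    ``extractor="frequency"`` candidates are ranked by raw count instead
    (score = 1/count).
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    sentences = split_sentences(text)
    if not sentences:
        return []
    cands = _candidates(sentences, ngram_max, stopwords)
    if not cands:
        return []

    scored: list[tuple[str, float]]
    if extractor == "frequency":
        scored = [(" ".join(gram), 1.0 / count) for gram, count in cands.items()]
    elif extractor == "yake":
        stats = term_statistics(sentences, stopwords=stopwords, window=window)
        scored = []
        for gram, count in cands.items():
            prod = 1.0
            total = 0.0
            for term in gram:
                s = stats[term].score
                prod *= s
                total += s
            scored.append((" ".join(gram), prod / (count * (1.0 + total))))
    else:
        raise ValueError(f"unknown extractor {extractor!r}; use 'yake' or 'frequency'")

    scored.sort(key=lambda kv: (kv[1], kv[0]))
    if dedup_threshold >= 1.0:
        return scored[:max_k]
    kept: list[tuple[str, float]] = []
    for kw, score in scored:
        if all(levenshtein_ratio(kw, prev) < dedup_threshold for prev, _ in kept):
            kept.append((kw, score))
            if len(kept) == max_k:
                break
    return kept
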