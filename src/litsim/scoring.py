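"""Per-category affinity scores for a document.

Two scorers are provided.  The similarity scorer concatenates each category's
reference keywords into a pseudo-text and computes the *soft cosine* between
that pseudo-text and the document over their union vocabulary:

    soft_cos(a, b; S) = aᵀ S b / (√(aᵀ S a) · √(bᵀ S b))

where a, b are bag-of-words count vectors and S is a symmetric, unit-diagonal
term-similarity kernel derived from word-embedding cosines (clipped below at a
threshold, then raised to an exponent; defaults 0.0 and 2.0).  With S = I the
soft cosine reduces exactly to the ordinary cosine.  The kernel lets a
document containing "tumour" earn credit against a keyword list containing
"glioma" in proportion to their embedding similarity.

The counting scorer simply counts occurrences of each category's keywords in
the normalized document token sequence, with multi-word keywords matched as
contiguous token runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingProvider
from .refbuild import ReferenceData
from .textprep import Document, normalize

DEFAULT_EXPONENT = 2.0
DEFAULT_THRESHOLD = 0.0


@dataclass(frozen=True)
class TermSimilarityMatrix:
    """Pairwise term similarities over an ordered vocabulary.

    S is symmetric with unit diagonal and entries in [0, 1]; it is the kernel
    of the soft cosine.
    """

    terms: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.terms)
        if self.S.shape != (n, n):
            raise ValueError(f"S shape {self.S.shape} does not match {n} terms")

    def index(self, term: str) -> int:
        return self.terms.index(term)


def term_similarity(t1: str, t2: str, provider: EmbeddingProvider,
                    exponent: float = DEFAULT_EXPONENT,
                    threshold: float = DEFAULT_THRESHOLD) -> float:
    """Kernel similarity between two terms, in [0, 1].

    Identical terms score 1 regardless of the provider.  Otherwise the
    embedding cosine is clipped below at ``threshold``, floored at 0 and
    raised to ``exponent``; a term without a vector scores 0 against any
    other term.
    """
    if t1 == t2:
        return 1.0
    if t1 not in provider or t2 not in provider:
        return 0.0
    v1, v2 = provider.get(t1), provider.get(t2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    cos = float(np.dot(v1, v2) / (n1 * n2))
    if cos < threshold:
        cos = 0.0
    return max(0.0, min(cos, 1.0)) ** exponent


def build_term_matrix(terms: list[str] | tuple[str, ...],
                      provider: EmbeddingProvider,
                      exponent: float = DEFAULT_EXPONENT,
                      threshold: float = DEFAULT_THRESHOLD) -> TermSimilarityMatrix:
    """Dense similarity kernel over an ordered vocabulary."""
    terms = tuple(terms)
    n = len(terms)
    vecs = np.zeros((n, provider.dim))
    has = np.zeros(n, dtype=bool)
    for i, t in enumerate(terms):
        if t in provider:
            v = provider.get(t)
            nv = np.linalg.norm(v)
            if nv > 0:
                vecs[i] = v / nv
                has[i] = True
    S = vecs @ vecs.T
    S[S < threshold] = 0.0
    np.clip(S, 0.0, 1.0, out=S)
    S **= exponent
    S[~has, :] = 0.0
    S[:, ~has] = 0.0
    np.fill_diagonal(S, 1.0)
    return TermSimilarityMatrix(terms, S)


def bow_vector(tokens, terms: tuple[str, ...]) -> np.ndarray:
    """Counts of ``tokens`` over the matrix term ordering (non-negative ints)."""
    index = {t: i for i, t in enumerate(terms)}
    v = np.zeros(len(terms), dtype=np.int64)
    for tok in tokens:
        i = index.get(tok)
        if i is not None:
            v[i] += 1
    return v


def soft_cosine(a: np.ndarray, b: np.ndarray, S: TermSimilarityMatrix | np.ndarray) -> float:
    """Soft cosine similarity of two aligned bag-of-words vectors.

    Raises ValueError on an all-zero vector (the similarity is undefined).
    """
    M = S.S if isinstance(S, TermSimilarityMatrix) else np.asarray(S)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not a.any() or not b.any():
        raise ValueError("soft cosine of an all-zero bag-of-words vector is undefined")
    num = float(a @ M @ b)
    den = np.sqrt(float(a @ M @ a)) * np.sqrt(float(b @ M @ b))
    return num / den


def keyword_pseudo_tokens(ref: ReferenceData, category: str) -> list[str]:
    """Tokens of the category's keyword pseudo-text: each list entry
    contributes its (phrase) tokens once, in list order."""
    toks: list[str] = []
    for kw in ref[category].keywords:
        toks.extend(kw.split(" "))
    return toks


def score_similarity(doc: Document, ref: ReferenceData,
                     provider: EmbeddingProvider,
                     exponent: float = DEFAULT_EXPONENT,
                     threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Soft-cosine similarity of the document to each category's keyword text.

    One value per category, in ReferenceData category order.  The kernel is
    built lazily over the union vocabulary of the document and the category's
    pseudo-text, which is exactly equivalent to a global-vocabulary kernel.
    A document sharing no vocabulary (and no embedding-linked mass) with a
    category scores 0 for it; an all-zero vector is returned for an empty
    document, flagging it as degenerate for the classifier.
    """
    doc_tokens = list(normalize(doc.combined_text))
    scores = np.zeros(len(ref.categories))
    if not doc_tokens:
        return scores
    for k, cat in enumerate(ref.categories):
        kw_tokens = keyword_pseudo_tokens(ref, cat)
        union = tuple(dict.fromkeys(doc_tokens + kw_tokens))
        S = build_term_matrix(union, provider, exponent, threshold)
        a = bow_vector(doc_tokens, S.terms)
        b = bow_vector(kw_tokens, S.terms)
        num = float(a @ S.S @ b)
        if num == 0.0:
            continue
        scores[k] = num / (np.sqrt(float(a @ S.S @ a)) * np.sqrt(float(b @ S.S @ b)))
    return scores


def count_hits(doc: Document, ref: ReferenceData) -> np.ndarray:
    """Occurrences of each category's keywords in the document.

    Multi-word keywords are matched as contiguous runs in the normalized
    token sequence; matches may overlap (every starting position counts).
    One count per category, in ReferenceData category order.
    """
    tokens = tuple(normalize(doc.combined_text))
    counts = np.zeros(len(ref.categories), dtype=np.int64)
    if not tokens:
        return counts
    # index unigram start positions once; phrases verified by extension
    positions: dict[str, list[int]] = {}
    for i, t in enumerate(tokens):
        positions.setdefault(t, []).append(i)
    for k, cat in enumerate(ref.categories):
        total = 0
        for kw in ref[cat].keywords:
            parts = kw.split(" ")
            for start in positions.get(parts[0], ()):
                if tokens[start:start + len(parts)] == tuple(parts):
                    total += 1
        counts[k] = total
    return counts
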