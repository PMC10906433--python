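"""Seeded synthetic corpora, toy embeddings, and paired noisy raters.

The generator emulates the structure the classifier exploits in real
bibliographic corpora: each category owns a vocabulary pool, every document
mixes tokens from its own pool (probability ``mixing``) with tokens from a
shared pool common to all categories, exemplar texts concentrate their
category's pool, and toy embeddings cluster by pool (own-pool vectors near a
category centroid, shared-pool vectors near the origin, so cross-category
term similarity is small but not zero).  Two simulated raters corrupt the
true labels with a symmetric uniform-confusion error.  Every draw is
reproducible from the spec's seed; documents, embeddings and raters use
independent named substreams so changing one component's draw count does not
perturb the others.

Token draws are i.i.d. within a document — no burstiness, no word order
semantics.  See docs/methods.md for what passing tests on this generator do
and do not show about real literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import InMemoryEmbeddings, save_word2vec_text
from .textprep import Document, write_records_csv

_SUBSTREAMS = {"docs": 0, "embeddings": 1, "raters": 2}


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic bundle.

    ``mixing`` is the probability a document token comes from its own
    category pool (the remainder from the shared pool); ``embedding_noise``
    is the within-category dispersion of token vectors around the category
    centroid.
    """

    n_categories: int = 5
    docs_per_category: int = 100
    vocab_per_category: int = 40
    shared_vocab_size: int = 120
    mixing: float = 0.8
    doc_length: int = 60
    embedding_dim: int = 16
    embedding_noise: float = 0.1
    rater_error: float = 0.1
    exemplar_length: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must be in [0, 1]")
        if not 0.0 <= self.rater_error < 1.0:
            raise ValueError("rater_error must be in [0, 1)")
        for name in ("n_categories", "docs_per_category", "vocab_per_category",
                     "shared_vocab_size", "doc_length", "embedding_dim",
                     "exemplar_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(f"cat{i}" for i in range(self.n_categories))


@dataclass(frozen=True)
class SyntheticBundle:
    spec: CorpusSpec
    documents: tuple[Document, ...]
    truth: dict[str, str]                   # record_id -> true category
    exemplars: dict[str, str]               # category -> exemplar text
    embeddings: InMemoryEmbeddings
    rater_a: tuple[str, ...]
    rater_b: tuple[str, ...]
    pools: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def truth_sequence(self) -> tuple[str, ...]:
        return tuple(self.truth[d.record_id] for d in self.documents)


def _rng(seed: int, substream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[substream],)))


def _pool_tokens(spec: CorpusSpec) -> tuple[dict[str, list[str]], list[str]]:
    own = {cat: [f"{cat}w{j}" for j in range(spec.vocab_per_category)]
           for cat in spec.categories}
    shared = [f"shw{j}" for j in range(spec.shared_vocab_size)]
    return own, shared


def generate(spec: CorpusSpec) -> SyntheticBundle:
    """Generate one fully reproducible bundle from a CorpusSpec."""
    own, shared = _pool_tokens(spec)

    rng = _rng(spec.seed, "docs")
    documents: list[Document] = []
    truth: dict[str, str] = {}
    year_lo, year_hi = 2000, 2020
    for cat in spec.categories:
        for d in range(spec.docs_per_category):
            from_own = rng.random(spec.doc_length) < spec.mixing
            tokens = [
                own[cat][rng.integers(len(own[cat]))] if o
                else shared[rng.integers(len(shared))]
                for o in from_own
            ]
            rid = f"{cat}-{d:04d}"
            cut = max(3, spec.doc_length // 6)
            documents.append(Document(
                record_id=rid,
                title=" ".join(tokens[:cut]),
                abstract=" ".join(tokens[cut:]),
                year=int(rng.integers(year_lo, year_hi + 1)),
            ))
            truth[rid] = cat

    # exemplars concentrate the own pool: skewed multinomial over own tokens
    # plus a pinch of shared vocabulary (removed again by reference dedup
    # only if it lands in >= 2 exemplars, which it will).
    exemplars: dict[str, str] = {}
    for cat in spec.categories:
        weights = 1.0 / np.arange(1, len(own[cat]) + 1)   # Zipf-ish
        weights /= weights.sum()
        n_own = int(spec.exemplar_length * 0.9)
        toks = list(rng.choice(own[cat], size=n_own, p=weights))
        toks += list(rng.choice(shared, size=spec.exemplar_length - n_own))
        rng.shuffle(toks)
        sentences = [" ".join(toks[i:i + 10]) for i in range(0, len(toks), 10)]
        exemplars[cat] = ". ".join(sentences) + "."

    erng = _rng(spec.seed, "embeddings")
    vectors: dict[str, np.ndarray] = {}
    for cat in spec.categories:
        centroid = erng.standard_normal(spec.embedding_dim)
        centroid /= np.linalg.norm(centroid)
        for tok in own[cat]:
            vectors[tok] = centroid + spec.embedding_noise * \
                erng.standard_normal(spec.embedding_dim)
    for tok in shared:
        vectors[tok] = spec.embedding_noise * erng.standard_normal(spec.embedding_dim)
    embeddings = InMemoryEmbeddings(vectors)

    truth_seq = [truth[d.record_id] for d in documents]
    rater_a, rater_b = simulate_raters(truth_seq, spec.rater_error, spec.seed,
                                       labels=spec.categories)
    return SyntheticBundle(
        spec=spec,
        documents=tuple(documents),
        truth=truth,
        exemplars=exemplars,
        embeddings=embeddings,
        rater_a=rater_a,
        rater_b=rater_b,
        pools={**{c: tuple(own[c]) for c in spec.categories},
               "shared": tuple(shared)},
    )


def simulate_raters(truth: Sequence[str], error_rate: float, seed: int, *,
                    labels: Sequence[str] | None = None
                    ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Two independent raters with symmetric uniform confusion.

    Each rater keeps the true label with probability 1 − error_rate and
    otherwise draws uniformly among the other labels.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    labels = tuple(labels) if labels is not None else tuple(sorted(set(truth)))
    rng = _rng(seed, "raters")

    def one_rater() -> tuple[str, ...]:
        out = []
        for t in truth:
            if rng.random() < error_rate and len(labels) > 1:
                others = [lab for lab in labels if lab != t]
                out.append(others[rng.integers(len(others))])
            else:
                out.append(t)
        return tuple(out)

    return one_rater(), one_rater()


def expected_rater_kappa(error_rate: float, n_labels: int) -> float:
    """Closed-form kappa between two independent uniform-confusion raters of a
    balanced corpus: used as the oracle for simulate_raters.

    With e = error_rate and L labels, a single rater reports label j given
    truth t with probability (1−e) if j = t else e/(L−1).  For balanced truth
    the raters' marginals are uniform, so p_e = 1/L, and
    p_o = (1−e)² + e²/(L−1).
    """
    if n_labels < 2:
        raise ValueError("need at least 2 labels")
    e = error_rate
    p_o = (1 - e) ** 2 + e ** 2 / (n_labels - 1)
    p_e = 1.0 / n_labels
    return (p_o - p_e) / (1.0 - p_e)


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> None:
    """Materialize a bundle in exactly the formats the real pipeline reads:
    corpus CSV, per-category exemplar .txt, word2vec text embeddings, truth CSV."""
    directory = Path(directory)
    (directory / "exemplars").mkdir(parents=True, exist_ok=True)
    write_records_csv(bundle.documents, directory / "corpus.csv")
    for cat, text in bundle.exemplars.items():
        (directory / "exemplars" / f"{cat}.txt").write_text(text, "utf-8")
    save_word2vec_text(
        {t: bundle.embeddings.get(t) for t in sorted(bundle.embeddings.vocabulary)},
        directory / "embeddings.w2v.txt")
    with (directory / "truth.csv").open("w", encoding="utf-8") as fh:
        fh.write("record_id,category,rater_a,rater_b\n")
        for doc, a, b in zip(bundle.documents, bundle.rater_a, bundle.rater_b):
            fh.write(f"{doc.record_id},{bundle.truth[doc.record_id]},{a},{b}\n")
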