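"""Word-embedding providers.

The scoring layer only needs a term → vector lookup of fixed dimension; any
key–vector store satisfies it.  Three implementations ship:

* :class:`InMemoryEmbeddings` — a plain dict, for tests and synthetic corpora;
* :func:`load_word2vec` — reads the word2vec keyed-vector interchange formats
  (text and binary), so a pretrained general-domain model such as a 300-d
  news-corpus model can be dropped in;
* :class:`HashedRandomEmbeddings` — deterministic pseudo-random unit vectors
  keyed by a hash of the term, useful as an always-available provider with no
  semantic structure.

Out-of-vocabulary terms are reported as absent (``term in provider`` is
False); they are never silently zero-filled.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract: fixed-dimension term → vector lookup with explicit vocabulary."""

    @property
    def dim(self) -> int: ...

    def __contains__(self, term: str) -> bool: ...

    def get(self, term: str) -> np.ndarray: ...


class InMemoryEmbeddings:
    """Embedding provider backed by a dict of equal-length vectors."""

    def __init__(self, vectors: Mapping[str, Iterable[float]]):
        if not vectors:
            raise ValueError("empty embedding map")
        self._vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}
        dims = {v.shape for v in self._vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"vectors must share one 1-D shape, got {dims}")
        self._dim = next(iter(dims))[0]

    @property
    def dim(self) -> int:
        return self._dim

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._vectors)

    def __contains__(self, term: str) -> bool:
        return term in self._vectors

    def get(self, term: str) -> np.ndarray:
        try:
            return self._vectors[term]
        except KeyError:
            raise KeyError(f"term {term!r} has no embedding vector") from None


class HashedRandomEmbeddings:
    """Deterministic pseudo-random unit vectors derived from a term hash.

    Every term is in-vocabulary; identical (term, dim, seed) always yields the
    same vector, across processes and platforms.
    """

    def __init__(self, dim: int = 32, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be positive")
        self._dim = dim
        self._seed = seed

    @property
    def dim(self) -> int:
        return self._dim

    def __contains__(self, term: str) -> bool:
        return True

    def get(self, term: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self._seed}:{term}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        v = rng.standard_normal(self._dim)
        return v / np.linalg.norm(v)


def load_word2vec(path: str | Path, binary: bool = False) -> InMemoryEmbeddings:
    """Read a word2vec keyed-vector file (header line ``n_words dim``).

    Text format: one ``word v1 ... vd`` line per term.  Binary format: the
    word as bytes up to a space, followed by ``dim`` little-endian float32s.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    if binary:
        with path.open("rb") as fh:
            n_words, dim = map(int, fh.readline().split())
            width = 4 * dim
            for _ in range(n_words):
                word = bytearray()
                while True:
                    ch = fh.read(1)
                    if ch in (b" ", b""):
                        break
                    if ch != b"\n":
                        word.extend(ch)
                vectors[word.decode("utf-8")] = np.frombuffer(
                    fh.read(width), dtype="<f4").astype(float)
    else:
        with path.open(encoding="utf-8") as fh:
            n_words, dim = map(int, fh.readline().split())
            for line in fh:
                parts = line.rstrip().split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"{path}: malformed line for {parts[0]!r}")
                vectors[parts[0]] = np.asarray(parts[1:], dtype=float)
    if len(vectors) != n_words:
        raise ValueError(f"{path}: header promised {n_words} words, "
                         f"found {len(vectors)}")
    return InMemoryEmbeddings(vectors)


def save_word2vec_text(provider_vectors: Mapping[str, np.ndarray],
                       path: str | Path) -> None:
    """Write vectors in the word2vec text interchange format."""
    items = list(provider_vectors.items())
    dim = len(np.asarray(items[0][1]))
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(items)} {dim}\n")
        for word, vec in items:
            fh.write(word + " " + " ".join(f"{x:.8g}" for x in np.asarray(vec)) + "\n")
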