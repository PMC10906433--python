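"""Build per-category reference keyword sets from exemplar texts.

The pipeline mirrors how a keyword anchor is prepared when no labelled
training corpus exists: each category's exemplar text (e.g. a textbook
section) is summarized into a ranked keyword list, keywords shared between
two or more categories are removed from *all* lists (so every surviving
keyword belongs to exactly one category), and each list is truncated to a
fixed per-category budget so no category is favoured merely by having more
keywords.  The canonical configuration extracts the top 1000 keywords per
category and keeps the top 500 after deduplication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from . import keywords as _kw
from .textprep import STOPWORDS, normalize

DEFAULT_FIRST_K = 1000
DEFAULT_BUDGET = 500


@dataclass(frozen=True)
class KeywordList:
    """Ranked keywords for one category; entries are (keyword, score), score
    ascending (lower = more relevant), no duplicates."""

    category: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        kws = [k for k, _ in self.entries]
        if len(set(kws)) != len(kws):
            raise ValueError(f"duplicate keywords in list for {self.category!r}")
        scores = [s for _, s in self.entries]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError(f"entries for {self.category!r} not sorted by score")

    @property
    def keywords(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.entries)


@dataclass(frozen=True)
class ReferenceData:
    """Per-category keyword lists after dedup and truncation.

    Invariants: keyword sets pairwise disjoint across categories; each list
    holds at most ``budget`` entries.  ``provenance`` records how the lists
    were built (first_k, budget, extractor, ngram_max).
    """

    categories: tuple[str, ...]
    lists: tuple[KeywordList, ...]
    budget: int
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(kl.category for kl in self.lists) != self.categories:
            raise ValueError("lists out of order with categories")
        sets = {kl.category: set(kl.keywords) for kl in self.lists}
        cats = list(self.categories)
        for i, a in enumerate(cats):
            if len(self.lists[i].entries) > self.budget:
                raise ValueError(f"list for {a!r} exceeds budget {self.budget}")
            for b in cats[i + 1:]:
                common = sets[a] & sets[b]
                if common:
                    raise ValueError(f"categories {a!r} and {b!r} share keywords: "
                                     f"{sorted(common)[:5]}")

    def __getitem__(self, category: str) -> KeywordList:
        return self.lists[self.categories.index(category)]


def extract_keywords(text: str, max_k: int, ngram_max: int = 3, *,
                     category: str = "", extractor: str = "yake",
                     stopwords: frozenset[str] = STOPWORDS) -> KeywordList:
    """Extract up to ``max_k`` ranked keywords (phrases up to ``ngram_max``
    words) from one exemplar text.

    Raises ValueError (naming the category) when the text is empty after
    normalization; returns fewer than ``max_k`` entries when the text has
    fewer candidates — the cap is an upper bound, never padded.
    """
    if not normalize(text).tokens:
        raise ValueError(f"exemplar text for category {category!r} is empty "
                         "after normalization")
    ranked = _kw.rank_keywords(text, max_k, ngram_max, extractor=extractor,
                               stopwords=stopwords)
    return KeywordList(category=category, entries=tuple(ranked))


def remove_shared(lists: Iterable[KeywordList]) -> list[KeywordList]:
    """Remove every keyword occurring in two or more lists — from all of them.

    Relative order within each list is preserved; the output lists are
    pairwise disjoint.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("remove_shared needs at least two keyword lists")
    membership: dict[str, int] = {}
    for kl in lists:
        for kw in kl.keywords:
            membership[kw] = membership.get(kw, 0) + 1
    return [
        KeywordList(kl.category,
                    tuple((k, s) for k, s in kl.entries if membership[k] == 1))
        for kl in lists
    ]


def build_reference(exemplars: Mapping[str, str],
                    first_k: int = DEFAULT_FIRST_K,
                    budget: int = DEFAULT_BUDGET,
                    ngram_max: int = 3, *,
                    extractor: str = "yake",
                    stopwords: frozenset[str] = STOPWORDS,
                    deny: Iterable[str] = (),
                    allow: Mapping[str, Iterable[str]] | None = None) -> ReferenceData:
    """Extract → dedup → truncate: turn exemplar texts into ReferenceData.

    Parameters
    ----------
    exemplars : mapping category -> exemplar text (at least two categories)
    first_k : keywords extracted per category before dedup (canonical 1000)
    budget : keywords kept per category after dedup (canonical 500)
    deny : keywords to drop everywhere (stands in for manual list review)
    allow : per-category keywords to force-append (score just above the
        list's worst) if they survived nowhere
    """
    if len(exemplars) < 2:
        raise ValueError("build_reference needs at least two categories")
    deny_set = {d.lower() for d in deny}
    extracted = [
        extract_keywords(text, first_k, ngram_max, category=cat,
                         extractor=extractor, stopwords=stopwords)
        for cat, text in exemplars.items()
    ]
    deduped = remove_shared(extracted)
    final: list[KeywordList] = []
    for kl in deduped:
        entries = [(k, s) for k, s in kl.entries if k not in deny_set][:budget]
        if allow and kl.category in allow:
            have = {k for k, _ in entries}
            worst = entries[-1][1] if entries else 0.0
            for extra in allow[kl.category]:
                extra = extra.lower()
                if extra not in have and len(entries) < budget:
                    worst += 1.0
                    entries.append((extra, worst))
                    have.add(extra)
        if not entries:
            raise ValueError(f"category {kl.category!r} has no keywords left "
                             "after deduplication")
        final.append(KeywordList(kl.category, tuple(entries)))
    return ReferenceData(
        categories=tuple(exemplars),
        lists=tuple(final),
        budget=budget,
        provenance={"first_k": first_k, "budget": budget, "ngram_max": ngram_max,
                    "extractor": extractor, "n_deny": len(deny_set)},
    )


def save_reference(ref: ReferenceData, directory: str | Path) -> None:
    """Serialize as keywords.tsv (keyword, score, category) + provenance.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "keywords.tsv").open("w", encoding="utf-8") as fh:
        fh.write("keyword\tscore\tcategory\n")
        for kl in ref.lists:
            for kw, score in kl.entries:
                fh.write(f"{kw}\t{score!r}\t{kl.category}\n")
    meta = {"categories": list(ref.categories), "budget": ref.budget,
            "provenance": dict(ref.provenance)}
    (directory / "provenance.json").write_text(json.dumps(meta, indent=2), "utf-8")


def load_reference(directory: str | Path) -> ReferenceData:
    directory = Path(directory)
    meta = json.loads((directory / "provenance.json").read_text("utf-8"))
    per_cat: dict[str, list[tuple[str, float]]] = {c: [] for c in meta["categories"]}
    with (directory / "keywords.tsv").open(encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            kw, score, cat = line.rstrip("\n").split("\t")
            per_cat[cat].append((kw, float(score)))
    return ReferenceData(
        categories=tuple(meta["categories"]),
        lists=tuple(KeywordList(c, tuple(per_cat[c])) for c in meta["categories"]),
        budget=meta["budget"],
        provenance=meta["provenance"],
    )
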