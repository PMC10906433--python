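"""Bibliographic record ingestion and text normalization.

Records arrive either as MEDLINE flat-file exports (``PMID``/``TI``/``AB``/``DP``
fields, as produced by PubMed's "PubMed format" download) or as CSV/TSV with
columns ``record_id,title,abstract,year``.  Title and abstract are joined with a
single space into the text that every downstream scorer consumes.  Records
missing both title and abstract carry no classifiable text and are dropped,
with the drop count reported to the caller.

Tokenization is deliberately minimal and reproducible: lowercase, split on
non-alphanumeric boundaries.  An English stopword list ships as package data so
results never depend on an external library version.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import Medline

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[a-z0-9]+")
_YEAR_RE = re.compile(r"\b(\d{4})\b")


def load_stopwords() -> frozenset[str]:
    """Return the packaged English stopword list."""
    text = resources.files("litsim.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


STOPWORDS: frozenset[str] = load_stopwords()


@dataclass(frozen=True)
class Document:
    """One bibliographic record admitted to classification.

    ``combined_text`` is the title and abstract joined with a single space;
    it is non-empty by construction (records lacking both fields are never
    turned into Documents).  ``year`` is the 4-digit publication year, or
    None when the source record carries none; such records are classified
    but excluded from trend aggregation.
    """

    record_id: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    combined_text: str = field(init=False)

    def __post_init__(self) -> None:
        joined = " ".join(part for part in (self.title.strip(), self.abstract.strip()) if part)
        if not joined:
            raise ValueError(f"record {self.record_id!r} has neither title nor abstract")
        object.__setattr__(self, "combined_text", joined)


@dataclass(frozen=True)
class TokenSequence:
    """Ordered lowercase word tokens from one record or exemplar text."""

    tokens: tuple[str, ...]
    source_id: str = ""

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


class ReadResult(NamedTuple):
    documents: list[Document]
    n_dropped: int


def normalize(text: str, remove_stopwords: bool = False, *, source_id: str = "",
              stopwords: frozenset[str] | None = None) -> TokenSequence:
    """Lowercase and tokenize ``text``; optionally drop stopwords.

    Total function: empty or punctuation-only input yields an empty sequence.
    """
    tokens = _WORD_RE.findall(text.lower())
    if remove_stopwords:
        sw = STOPWORDS if stopwords is None else stopwords
        tokens = [t for t in tokens if t not in sw]
    return TokenSequence(tuple(tokens), source_id=source_id)


def _parse_year(raw: str | None) -> int | None:
    if not raw:
        return None
    m = _YEAR_RE.search(str(raw))
    return int(m.group(1)) if m else None


def _admit(record_id: str, title: str, abstract: str, year_raw, out: list[Document]) -> bool:
    """Append a Document if the record has any text; return whether admitted."""
    if not (title.strip() or abstract.strip()):
        return False
    out.append(Document(record_id=record_id, title=title.strip(), abstract=abstract.strip(),
                        year=_parse_year(year_raw)))
    return True


def read_records(path: str | Path, format: str = "csv") -> ReadResult:
    """Read bibliographic records from ``path``.

    Parameters
    ----------
    path : file path
    format : {"csv", "medline"}
        ``csv`` expects a header with columns record_id,title,abstract,year
        (tab-delimited files are auto-detected); ``medline`` expects the
        PubMed MEDLINE flat-file format.

    Returns
    -------
    ReadResult
        ``documents`` in file order and ``n_dropped``, the number of records
        excluded because both title and abstract were missing.
    """
    path = Path(path)
    docs: list[Document] = []
    dropped = 0
    if format == "medline":
        with path.open(encoding="utf-8") as fh:
            for i, rec in enumerate(Medline.parse(fh)):
                rid = rec.get("PMID") or f"medline-{i}"
                if not _admit(rid, rec.get("TI", ""), rec.get("AB", ""), rec.get("DP"), docs):
                    dropped += 1
                    logger.warning("dropping record %s: no title and no abstract", rid)
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            sample = fh.read(4096)
            fh.seek(0)
            delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
            reader = csv.DictReader(fh, delimiter=delimiter)
            required = {"record_id", "title", "abstract"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(
                    f"{path}: expected columns record_id,title,abstract[,year], "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                if not _admit(row["record_id"], row.get("title") or "", row.get("abstract") or "",
                              row.get("year"), docs):
                    dropped += 1
                    logger.warning("dropping record %s: no title and no abstract",
                                   row["record_id"])
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'medline'")
    seen: set[str] = set()
    for d in docs:
        if d.record_id in seen:
            raise ValueError(f"duplicate record_id {d.record_id!r} in {path}")
        seen.add(d.record_id)
    return ReadResult(docs, dropped)


def write_records_csv(documents: Iterable[Document], path: str | Path) -> None:
    """Write documents as the CSV dialect ``read_records`` reads back."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "title", "abstract", "year"])
        for d in documents:
            writer.writerow([d.record_id, d.title, d.abstract,
                             "" if d.year is None else d.year])
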