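"""Category assignment with an abstention gate, batch classification, trends.

A score vector alone does not justify an assignment: when no category stands
out, the record belongs in the reserve category ETC ("everything else").  The
default gate is a two-sided one-sample t-test of the K−1 non-maximal scores
against the maximal score (df = K−2): only when the maximum is significantly
separated from the rest (p < alpha, canonically 0.05) is the record assigned
to the argmax category; otherwise it abstains to ETC.  This is one literal
reading of "compare the scores with a t-test" — a t-test over a handful of
scalar scores is statistically unusual, and a score-margin rule is provided
as an alternative gate for users who reject the t-test framing (see
docs/methods.md).

Conventions for degenerate score vectors are explicit:

* tie at the maximum, or all scores equal → ETC (nothing stands out);
* the K−1 remaining scores identical and *below* the max (zero variance) →
  assign the argmax with gate_p = 0 (infinite separation in t units);
* all-zero score vector (document shares nothing with any category) → ETC,
  flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .embeddings import EmbeddingProvider
from .refbuild import ReferenceData
from .scoring import count_hits, score_similarity
from .textprep import Document

ETC = "ETC"
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ClassificationDecision:
    record_id: str
    assigned: str
    scores: tuple[float, ...]
    categories: tuple[str, ...]
    gate_p: float
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class TrendSeries:
    """Per-year record counts for one category, optionally extended by a
    linear forecast (years strictly after the observed range)."""

    category: str
    years: tuple[int, ...]
    counts: tuple[int, ...]
    forecast: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.forecast and self.years and self.forecast[0][0] <= max(self.years):
            raise ValueError("forecast years must follow observed years")


def decide(scores: Sequence[float], categories: Sequence[str], *,
           record_id: str = "", alpha: float = DEFAULT_ALPHA,
           rule: str = "one_sample_vs_max", margin: float = 0.2,
           method: str = "similarity") -> ClassificationDecision:
    """Turn a per-category score vector into an assignment or ETC.

    Parameters
    ----------
    scores, categories : aligned score vector and category labels
    alpha : significance level of the gate, in (0, 1)
    rule : "one_sample_vs_max" (default; needs >= 3 categories) or "margin"
        (assign when (max − second) / max > ``margin``; works for K >= 2)
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    scores_arr = np.asarray(scores, dtype=float)
    categories = tuple(categories)
    if scores_arr.shape != (len(categories),):
        raise ValueError("scores and categories must align")

    def dec(assigned: str, p: float, degenerate: bool = False) -> ClassificationDecision:
        return ClassificationDecision(record_id, assigned, tuple(scores_arr),
                                      categories, p, method, degenerate)

    if not scores_arr.any():
        return dec(ETC, 1.0, degenerate=True)

    m = int(np.argmax(scores_arr))
    top = scores_arr[m]
    rest = np.delete(scores_arr, m)
    if np.any(rest == top):  # tie at the maximum
        return dec(ETC, 1.0)

    if rule == "margin":
        gap = (top - rest.max()) / top if top != 0 else 0.0
        return dec(categories[m], 0.0) if gap > margin else dec(ETC, 1.0)
    if rule != "one_sample_vs_max":
        raise ValueError(f"unknown gate rule {rule!r}")
    if len(categories) < 3:
        raise ValueError("the one_sample_vs_max gate needs >= 3 categories; "
                         "use rule='margin' for 2 categories")

    if np.all(rest == rest[0]):  # zero variance strictly below the max
        return dec(categories[m], 0.0)
    p = float(stats.ttest_1samp(rest, popmean=top).pvalue)
    return dec(categories[m], p) if p < alpha else dec(ETC, p)


def classify_corpus(docs: Iterable[Document], ref: ReferenceData,
                    method: str = "similarity",
                    provider: EmbeddingProvider | None = None,
                    alpha: float = DEFAULT_ALPHA, *,
                    rule: str = "one_sample_vs_max", margin: float = 0.2,
                    other_category: str | None = None) -> list[ClassificationDecision]:
    """Classify every document; never abort the batch on a single record.

    A record whose scoring fails (or whose score vector is all zero) becomes
    an ETC decision flagged degenerate.  When the reference includes a
    catch-all list (``other_category``), winning on it also maps to ETC.
    """
    if method == "similarity":
        if provider is None:
            raise ValueError("the similarity method requires an embedding provider")
    elif method != "counting":
        raise ValueError(f"unknown method {method!r}; use 'similarity' or 'counting'")
    decisions = []
    for doc in docs:
        try:
            if method == "similarity":
                scores = score_similarity(doc, ref, provider)
            else:
                scores = count_hits(doc, ref).astype(float)
            d = decide(scores, ref.categories, record_id=doc.record_id,
                       alpha=alpha, rule=rule, margin=margin, method=method)
        except Exception:
            d = ClassificationDecision(doc.record_id, ETC,
                                       (0.0,) * len(ref.categories),
                                       tuple(ref.categories), 1.0, method,
                                       degenerate=True)
        if other_category is not None and d.assigned == other_category:
            d = replace(d, assigned=ETC)
        decisions.append(d)
    return decisions


def yearly_counts(decisions: Sequence[ClassificationDecision],
                  docs: Sequence[Document],
                  categories: Sequence[str] | None = None
                  ) -> tuple[list[TrendSeries], int]:
    """Per-category, per-year record counts.

    Records without a publication year are excluded; their number is the
    second return value.  The sum of all counts equals the number of
    year-bearing records.
    """
    year_of = {d.record_id: d.year for d in docs}
    tallies: dict[str, dict[int, int]] = {}
    excluded = 0
    for d in decisions:
        year = year_of.get(d.record_id)
        if year is None:
            excluded += 1
            continue
        tallies.setdefault(d.assigned, {})
        tallies[d.assigned][year] = tallies[d.assigned].get(year, 0) + 1
    if categories is None:
        named = sorted(c for c in tallies if c != ETC)
        categories = named + ([ETC] if ETC in tallies else [])
    series = []
    for cat in categories:
        per_year = tallies.get(cat, {})
        years = tuple(sorted(per_year))
        series.append(TrendSeries(cat, years, tuple(per_year[y] for y in years)))
    return series, excluded


def linear_forecast(series: TrendSeries, horizon: int) -> TrendSeries:
    """Extend a series by an ordinary-least-squares line fit.

    The line is fit on the full observed (year, count) range and evaluated at
    the next ``horizon`` years; predictions are floored at 0 because negative
    publication counts are meaningless.
    """
    if len(series.years) < 2:
        raise ValueError("linear_forecast needs at least two observed years")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    slope, intercept = np.polyfit(np.asarray(series.years, dtype=float),
                                  np.asarray(series.counts, dtype=float), 1)
    last = max(series.years)
    forecast = tuple(
        (year, float(max(0.0, slope * year + intercept)))
        for year in range(last + 1, last + 1 + horizon)
    )
    return TrendSeries(series.category, series.years, series.counts, forecast)


def decisions_to_rows(decisions: Sequence[ClassificationDecision]
                      ) -> list[dict[str, object]]:
    """Flatten decisions for CSV export (record_id, assigned, gate_p, scores)."""
    rows = []
    for d in decisions:
        row: dict[str, object] = {"record_id": d.record_id, "assigned": d.assigned,
                                  "gate_p": d.gate_p, "method": d.method}
        for cat, s in zip(d.categories, d.scores):
            row[f"score_{cat}"] = s
        rows.append(row)
    return rows
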