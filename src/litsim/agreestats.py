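"""Inter-rater agreement and diagnostic statistics for paired classifications.

Everything operates on a K×K contingency table cross-classifying the same
records by two raters (or one method against a reference standard): rows are
rater 1, columns are rater 2 (the reference).  The battery comprises

* Cohen's kappa with its standard error under the null of chance agreement,
  the z statistic kappa/se0 and the one-sided normal p-value,
* Bowker's test of table symmetry,
* the Stuart–Maxwell test of overall marginal homogeneity,
* per-category McNemar tests (asymptotic chi-square and exact binomial),
* per-category sensitivity and specificity with the columns as truth.

The null standard error of kappa is the chance-agreement form

    se0 = sqrt(p_e + p_e² − Σᵢ pᵢ₊ p₊ᵢ (pᵢ₊ + p₊ᵢ)) / ((1 − p_e) √n),

with pᵢ₊, p₊ᵢ the marginal proportions — the form used to test kappa = 0
(the non-null standard error is out of scope).

A 6×6 table cross-classifying a similarity-based classifier against a
human reference standard over five neurosurgical subspecialties plus ETC
ships as package data (``load_example_table``) and exercises every statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    """K×K cross-classification counts: rows = rater 1, columns = rater 2."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.counts.sum() < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @classmethod
    def from_pairs(cls, rater1: Sequence[str], rater2: Sequence[str],
                   labels: Sequence[str]) -> "ContingencyTable":
        if len(rater1) != len(rater2):
            raise ValueError(f"paired sequences differ in length: "
                             f"{len(rater1)} vs {len(rater2)}")
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for a, b in zip(rater1, rater2):
            counts[idx[a], idx[b]] += 1
        return cls(tuple(labels), counts)

    @classmethod
    def from_csv(cls, path_or_buffer) -> "ContingencyTable":
        """Read a table whose first row and first column hold the labels."""
        df = pd.read_csv(path_or_buffer, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels must match in order")
        return cls(tuple(df.columns), df.to_numpy(dtype=np.int64))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)


def load_example_table() -> ContingencyTable:
    """The packaged 6×6 similarity-method vs reference-standard table."""
    text = resources.files("litsim.data").joinpath(
        "similarity_vs_reference_6x6.csv").read_text("utf-8")
    return ContingencyTable.from_csv(StringIO(text))


@dataclass(frozen=True)
class KappaResult:
    p_o: float
    p_e: float
    kappa: float
    se0: float
    z: float
    p_value: float


@dataclass(frozen=True)
class SymmetryHomogeneityResult:
    bowker_chi2: float
    bowker_df: int
    bowker_p: float
    sm_chi2: float
    sm_df: int
    sm_p: float


@dataclass(frozen=True)
class McNemarResult:
    category: str
    b: int          # rater 1 says category, rater 2 does not
    c: int          # rater 2 says category, rater 1 does not
    chi2: float
    p_asym: float
    p_exact: float
    degenerate: bool = False  # b + c == 0: no discordant pairs


@dataclass(frozen=True)
class CategoryDiagnostics:
    category: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float


def cohen_kappa(t: ContingencyTable) -> KappaResult:
    """Cohen's kappa with null SE, z and one-sided p (z-test of kappa = 0)."""
    n = t.n
    p = t.counts / n
    p_o = float(np.trace(p))
    pi, pj = t.row_totals / n, t.col_totals / n
    p_e = float(pi @ pj)
    if 1.0 - p_e <= 0.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se0 = math.sqrt(p_e + p_e ** 2 - float((pi * pj * (pi + pj)).sum())) \
        / ((1.0 - p_e) * math.sqrt(n))
    z = kappa / se0
    return KappaResult(p_o, p_e, kappa, se0, z, float(stats.norm.sf(z)))


def kappa_from_summary(p_o: float, p_e: float) -> float:
    """Kappa from printed observed/expected agreement proportions."""
    if not 0.0 <= p_e < 1.0:
        raise ValueError("p_e must be in [0, 1)")
    return (p_o - p_e) / (1.0 - p_e)


def bowker_symmetry(t: ContingencyTable) -> tuple[float, int, float]:
    """Bowker's chi-square test that the table is symmetric.

    Only unordered pairs with at least one discordant count contribute; df is
    the number of such pairs.  With no qualifying pair the statistic is 0 on
    0 df and the p-value is NaN (undefined).
    """
    c = t.counts
    chi2, df = 0.0, 0
    for i in range(len(t.labels)):
        for j in range(i + 1, len(t.labels)):
            s = c[i, j] + c[j, i]
            if s > 0:
                chi2 += (c[i, j] - c[j, i]) ** 2 / s
                df += 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return chi2, df, p


def stuart_maxwell(t: ContingencyTable) -> tuple[float, int, float]:
    """Stuart–Maxwell chi-square test of marginal homogeneity.

    d holds the row−column marginal differences for K−1 categories (the last
    is dropped; the statistic is invariant to the choice when the covariance
    is nonsingular); categories absent from both margins are removed before
    inversion, reducing df accordingly.
    """
    c = t.counts.astype(float)
    k = len(t.labels)
    if k < 2:
        raise ValueError("Stuart-Maxwell needs at least 2 categories")
    r, s = t.row_totals.astype(float), t.col_totals.astype(float)
    keep = [i for i in range(k) if r[i] + s[i] > 0]
    dropped_labels = [t.labels[i] for i in range(k) if r[i] + s[i] == 0]
    keep = keep[:-1] if len(keep) > 1 else keep  # drop one redundant category
    d = np.array([r[i] - s[i] for i in keep])
    V = np.empty((len(keep), len(keep)))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            V[a, b] = r[i] + s[i] - 2 * c[i, i] if i == j else -(c[i, j] + c[j, i])
    if not d.any():
        # equal margins: homogeneity holds exactly, even when V is singular
        # (e.g. a perfect-agreement table has V = 0)
        chi2 = 0.0
    else:
        try:
            chi2 = float(d @ np.linalg.solve(V, d))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "Stuart-Maxwell covariance singular after dropping empty "
                f"categories {dropped_labels or '(none)'}") from exc
    df = len(keep)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def mcnemar_category(t: ContingencyTable, category: str) -> McNemarResult:
    """McNemar test of marginal homogeneity for one category vs the rest.

    The table is collapsed to 2×2; b and c are the discordant counts.  The
    exact p doubles the smaller binomial(b+c, ½) tail, capped at 1.
    """
    i = t.labels.index(category)
    diag = int(t.counts[i, i])
    b = int(t.row_totals[i]) - diag
    c = int(t.col_totals[i]) - diag
    if b + c == 0:
        return McNemarResult(category, b, c, 0.0, 1.0, 1.0, degenerate=True)
    chi2 = (b - c) ** 2 / (b + c)
    p_asym = float(stats.chi2.sf(chi2, 1))
    m = b + c
    tail = sum(math.comb(m, k) for k in range(min(b, c) + 1)) * 0.5 ** m
    return McNemarResult(category, b, c, chi2, p_asym, min(1.0, 2.0 * tail))


def sensitivity_specificity(t: ContingencyTable, category: str) -> CategoryDiagnostics:
    """Per-category sensitivity and specificity, columns (rater 2) as truth."""
    i = t.labels.index(category)
    tp = int(t.counts[i, i])
    fn = int(t.col_totals[i]) - tp
    fp = int(t.row_totals[i]) - tp
    tn = t.n - tp - fn - fp
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return CategoryDiagnostics(category, tp, fp, fn, tn, sens, spec)


@dataclass(frozen=True)
class AgreementReport:
    table: ContingencyTable
    kappa: KappaResult
    symmetry: SymmetryHomogeneityResult
    mcnemar: tuple[McNemarResult, ...]
    diagnostics: tuple[CategoryDiagnostics, ...]

    def to_dict(self) -> dict:
        return {
            "n": self.table.n,
            "kappa": vars(self.kappa),
            "symmetry_homogeneity": vars(self.symmetry),
            "mcnemar": {m.category: vars(m) for m in self.mcnemar},
            "diagnostics": {d.category: vars(d) for d in self.diagnostics},
        }

    def format_text(self) -> str:
        """Human-readable summary mirroring the usual agreement-table layout."""
        k = self.kappa
        lines = [
            f"n = {self.table.n}",
            f"Agreement {100 * k.p_o:.2f}%   Expected {100 * k.p_e:.2f}%   "
            f"Kappa {k.kappa:.4f}   SE {k.se0:.4f}   Z {k.z:.2f}   "
            f"Prob>Z {k.p_value:.4f}",
            f"Symmetry (Bowker)        chi2 {self.symmetry.bowker_chi2:.2f}  "
            f"df {self.symmetry.bowker_df}  p {self.symmetry.bowker_p:.4f}",
            f"Marginal homogeneity (SM) chi2 {self.symmetry.sm_chi2:.2f}  "
            f"df {self.symmetry.sm_df}  p {self.symmetry.sm_p:.4f}",
            "category            b   c   chi2    p_asym  p_exact  sens     spec",
        ]
        for m, d in zip(self.mcnemar, self.diagnostics):
            lines.append(
                f"{m.category:<18}{m.b:>4}{m.c:>4}  {m.chi2:6.2f}  {m.p_asym:.4f}"
                f"  {m.p_exact:.4f}  {100 * d.sensitivity:6.2f}%  "
                f"{100 * d.specificity:6.2f}%")
        return "\n".join(lines)


def restrict_to_agreement(ref_a: Sequence[str], ref_b: Sequence[str],
                          *other: Sequence[str]) -> tuple[Sequence[str], ...]:
    """Keep only positions where two reference raters agree.

    Returns the agreed reference labels followed by each of ``other``
    restricted to the same positions — the usual construction of a reference
    standard from two imperfect raters.
    """
    if len(ref_a) != len(ref_b) or any(len(o) != len(ref_a) for o in other):
        raise ValueError("all label sequences must have equal length")
    keep = [i for i, (a, b) in enumerate(zip(ref_a, ref_b)) if a == b]
    agreed = [ref_a[i] for i in keep]
    return (agreed, *([seq[i] for i in keep] for seq in other))


def agreement_report(decisions_a: Sequence[str], decisions_b: Sequence[str],
                     labels: Sequence[str]) -> AgreementReport:
    """Build the contingency table and run the full statistic battery."""
    table = ContingencyTable.from_pairs(decisions_a, decisions_b, labels)
    return report_from_table(table)


def report_from_table(table: ContingencyTable) -> AgreementReport:
    bw = bowker_symmetry(table)
    sm = stuart_maxwell(table)
    return AgreementReport(
        table=table,
        kappa=cohen_kappa(table),
        symmetry=SymmetryHomogeneityResult(*bw, *sm),
        mcnemar=tuple(mcnemar_category(table, c) for c in table.labels),
        diagnostics=tuple(sensitivity_specificity(table, c) for c in table.labels),
    )
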