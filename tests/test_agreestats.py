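"""Agreement battery: kappa, Bowker, Stuart-Maxwell, McNemar, diagnostics.

The packaged 6x6 example table (similarity method vs human reference
standard, n=79) carries known published values for every statistic; random
tables are cross-checked against statsmodels and brute-force enumerations.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.contingency_tables import SquareTable, mcnemar
from statsmodels.stats.inter_rater import cohens_kappa

import litsim as ls
from litsim.agreestats import ContingencyTable


def _random_table(rng, k, low=1, high=12):
    return ContingencyTable(tuple(f"c{i}" for i in range(k)),
                            rng.integers(low, high, size=(k, k)).astype(np.int64))


# ---------------------------------------------------------------- kappa

def test_kappa_example_table(example_table):
    r = ls.cohen_kappa(example_table)
    assert round(100 * r.p_o, 2) == 75.95
    assert round(100 * r.p_e, 2) == 19.29
    assert round(r.kappa, 4) == 0.7020
    assert round(r.se0, 4) == 0.0526
    assert round(r.z, 2) == 13.35
    assert r.p_value < 1e-6


def test_kappa_perfect_and_chance():
    diag = ContingencyTable(("a", "b", "c"), np.diag([5, 3, 2]).astype(np.int64))
    assert ls.cohen_kappa(diag).kappa == pytest.approx(1.0)
    flat = ContingencyTable(("a", "b"), np.ones((2, 2), dtype=np.int64))
    r = ls.cohen_kappa(flat)
    assert (r.p_o, r.p_e, r.kappa) == (0.5, 0.5, pytest.approx(0.0))


def test_kappa_cross_checked_against_statsmodels():
    rng = np.random.default_rng(3)
    for _ in range(20):
        t = _random_table(rng, 4)
        mine = ls.cohen_kappa(t)
        ref = cohens_kappa(t.counts)
        assert mine.kappa == pytest.approx(ref.kappa, rel=1e-10)
        assert mine.se0 == pytest.approx(ref.std_kappa0, rel=1e-10)
        assert mine.z == pytest.approx(ref.z_value, rel=1e-10)


def test_kappa_from_summary():
    # published values truncate the 4th decimal, hence abs tolerance 1e-4
    assert ls.kappa_from_summary(0.79, 0.2265) == pytest.approx(0.7285, abs=1e-4)
    assert ls.kappa_from_summary(0.6709, 0.1812) == pytest.approx(0.5980, abs=1e-4)
    assert ls.kappa_from_summary(0.4, 0.4) == 0.0
    with pytest.raises(ValueError):
        ls.kappa_from_summary(1.0, 1.0)


# ------------------------------------------------------- symmetry / SM

def test_bowker_example_table(example_table):
    chi2, df, p = ls.bowker_symmetry(example_table)
    assert chi2 == pytest.approx(17.0)
    assert df == 8
    assert p == pytest.approx(0.0301, abs=5e-5)


def test_bowker_symmetric_table_is_zero():
    c = np.array([[3, 2, 1], [2, 4, 5], [1, 5, 6]], dtype=np.int64)
    chi2, df, p = ls.bowker_symmetry(ContingencyTable(("a", "b", "c"), c))
    assert chi2 == 0.0 and df == 3 and p == pytest.approx(1.0)


def test_bowker_random_tables_match_pair_loop_and_statsmodels():
    rng = np.random.default_rng(7)
    for _ in range(20):
        t = _random_table(rng, 4, low=1)  # all pair sums positive
        chi2, df, p = ls.bowker_symmetry(t)
        brute = sum((t.counts[i, j] - t.counts[j, i]) ** 2 /
                    (t.counts[i, j] + t.counts[j, i])
                    for i, j in itertools.combinations(range(4), 2))
        assert chi2 == pytest.approx(brute)
        sm = SquareTable(t.counts.copy(), shift_zeros=False).symmetry()
        assert chi2 == pytest.approx(float(sm.statistic)) and df == int(sm.df)


def test_stuart_maxwell_example_table(example_table):
    chi2, df, p = ls.stuart_maxwell(example_table)
    assert round(chi2, 1) == 15.5
    assert df == 5
    assert round(p, 4) == 0.0084


def test_stuart_maxwell_equal_margins_zero():
    c = np.array([[5, 2, 3], [2, 6, 1], [3, 1, 4]], dtype=np.int64)  # symmetric
    chi2, _, _ = ls.stuart_maxwell(ContingencyTable(("a", "b", "c"), c))
    assert chi2 == pytest.approx(0.0)


def test_stuart_maxwell_reduces_to_mcnemar_on_2x2():
    rng = np.random.default_rng(13)
    for _ in range(50):
        t = _random_table(rng, 2, low=1, high=20)
        chi2, df, _ = ls.stuart_maxwell(t)
        b, c = int(t.counts[0, 1]), int(t.counts[1, 0])
        assert df == 1
        assert chi2 == pytest.approx((b - c) ** 2 / (b + c))


def test_stuart_maxwell_cross_checked_against_statsmodels():
    rng = np.random.default_rng(19)
    for _ in range(20):
        t = _random_table(rng, 5)
        chi2, df, p = ls.stuart_maxwell(t)
        ref = SquareTable(t.counts.copy(), shift_zeros=False).homogeneity()
        assert chi2 == pytest.approx(float(ref.statistic), rel=1e-9)
        assert df == int(ref.df)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_label_permutation_invariance(example_table):
    rng = np.random.default_rng(23)
    perm = rng.permutation(len(example_table.labels))
    permuted = ContingencyTable(
        tuple(example_table.labels[i] for i in perm),
        example_table.counts[np.ix_(perm, perm)].copy())
    assert ls.cohen_kappa(permuted).kappa == \
        pytest.approx(ls.cohen_kappa(example_table).kappa)
    assert ls.bowker_symmetry(permuted)[0] == \
        pytest.approx(ls.bowker_symmetry(example_table)[0])
    assert ls.stuart_maxwell(permuted)[0] == \
        pytest.approx(ls.stuart_maxwell(example_table)[0])


def test_transpose_swaps_diagnostics_but_fixes_chi2(example_table):
    tr = ContingencyTable(example_table.labels, example_table.counts.T.copy())
    assert ls.cohen_kappa(tr).kappa == pytest.approx(
        ls.cohen_kappa(example_table).kappa)
    assert ls.bowker_symmetry(tr)[0] == pytest.approx(
        ls.bowker_symmetry(example_table)[0])
    assert ls.stuart_maxwell(tr)[0] == pytest.approx(
        ls.stuart_maxwell(example_table)[0])
    for lab in example_table.labels:
        d, dt = ls.sensitivity_specificity(example_table, lab), \
            ls.sensitivity_specificity(tr, lab)
        assert (d.tp, d.fp, d.fn) == (dt.tp, dt.fn, dt.fp)


# ----------------------------------------------------------- McNemar

@pytest.mark.parametrize("category,chi2,p_exact", [
    ("ETC", 12.25, 0.0005),
    ("Cranial Trauma", 5.44, 0.0391),
    ("Vascular", 3.00, 0.2500),
    ("Spine", 0.33, 1.0000),
    ("Oncology", 1.80, 0.3750),
    ("Functional", 2.00, 0.5000),
])
def test_mcnemar_example_table(example_table, category, chi2, p_exact):
    r = ls.mcnemar_category(example_table, category)
    assert round(r.chi2, 2) == chi2
    assert round(r.p_exact, 4) == p_exact


def test_mcnemar_balanced_discordance():
    c = np.array([[4, 3], [3, 4]], dtype=np.int64)
    r = ls.mcnemar_category(ContingencyTable(("x", "y"), c), "x")
    assert r.chi2 == 0.0 and r.p_exact == 1.0


def test_mcnemar_no_discordance_flagged():
    c = np.diag([5, 5]).astype(np.int64)
    r = ls.mcnemar_category(ContingencyTable(("x", "y"), c), "x")
    assert r.degenerate and r.chi2 == 0.0 and r.p_exact == 1.0


def test_mcnemar_exact_equals_binomial_enumeration():
    """All discordant splits with b+c <= 20 against direct enumeration of the
    binomial(b+c, 1/2) distribution (and statsmodels' exact mcnemar)."""
    for m in range(1, 21):
        for b in range(m + 1):
            c = m - b
            counts = np.array([[3, b], [c, 2]], dtype=np.int64)
            r = ls.mcnemar_category(ContingencyTable(("x", "y"), counts), "x")
            pmf = [math.comb(m, k) * 0.5 ** m for k in range(m + 1)]
            expected = min(1.0, 2.0 * sum(pmf[: min(b, c) + 1]))
            assert r.p_exact == pytest.approx(expected, rel=1e-12)
            sm_p = float(mcnemar(counts, exact=True).pvalue)
            assert r.p_exact == pytest.approx(sm_p, rel=1e-9)


# ------------------------------------------------------- diagnostics

@pytest.mark.parametrize("category,sens,spec", [
    ("ETC", 44.44, 98.08),
    ("Vascular", 100.00, 95.71),
    ("Spine", 86.67, 98.44),
    ("Oncology", 95.00, 93.22),
    ("Functional", 100.00, 97.37),
    ("Cranial Trauma", 80.00, 89.19),
])
def test_sensitivity_specificity_example_table(example_table, category, sens, spec):
    d = ls.sensitivity_specificity(example_table, category)
    assert round(100 * d.sensitivity, 2) == sens
    assert round(100 * d.specificity, 2) == spec


def test_perfect_diagonal_diagnostics():
    t = ContingencyTable(("a", "b"), np.diag([7, 3]).astype(np.int64))
    for lab in t.labels:
        d = ls.sensitivity_specificity(t, lab)
        assert d.sensitivity == 1.0 and d.specificity == 1.0


# ---------------------------------------------------------- reports

def test_agreement_report_identical_sequences():
    seq = ["a", "b", "a", "c", "b", "a"]
    rep = ls.agreement_report(seq, seq, labels=("a", "b", "c"))
    assert rep.kappa.kappa == pytest.approx(1.0)
    assert all(m.chi2 == 0.0 for m in rep.mcnemar)


def test_agreement_report_round_trips_table(example_table):
    """Pairs reconstructing the example table reproduce the whole battery."""
    pairs = [(example_table.labels[i], example_table.labels[j])
             for i in range(6) for j in range(6)
             for _ in range(int(example_table.counts[i, j]))]
    a, b = zip(*pairs)
    rep = ls.agreement_report(a, b, labels=example_table.labels)
    assert np.array_equal(rep.table.counts, example_table.counts)
    assert round(rep.kappa.kappa, 4) == 0.7020
    assert round(rep.symmetry.sm_chi2, 1) == 15.5


def test_restrict_to_agreement():
    ra = ["a", "b", "c", "a"]
    rb = ["a", "x", "c", "b"]
    other = ["p", "q", "r", "s"]
    agreed, sub = ls.restrict_to_agreement(ra, rb, other)
    assert agreed == ["a", "c"] and sub == ["p", "r"]
    with pytest.raises(ValueError):
        ls.restrict_to_agreement(ra, rb[:2])


def test_simulated_raters_kappa_matches_closed_form():
    """Mean kappa over 500 seeded replicates of 20% symmetric disagreement is
    within 0.05 of the uniform-confusion closed form."""
    from litsim.synthdata import expected_rater_kappa
    labels = tuple("abcdef")
    truth = [labels[i % 6] for i in range(120)]
    expected = expected_rater_kappa(0.2, 6)
    kappas = []
    for seed in range(500):
        a, b = ls.simulate_raters(truth, 0.2, seed, labels=labels)
        kappas.append(ls.cohen_kappa(
            ContingencyTable.from_pairs(a, b, labels)).kappa)
    assert abs(np.mean(kappas) - expected) < 0.05
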