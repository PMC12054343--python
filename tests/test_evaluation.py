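"""Accuracy scoring, MAF computation and binning, allelic coverage."""

import math

import numpy as np
import pytest

from hlablend import (
    GenotypeCall,
    MafBinSpec,
    PosteriorTable,
    TruthTable,
    accuracy,
    allele_coverage,
    binned_accuracy,
    compute_maf,
    minor_frequency,
    pair_accuracy,
)
from hlablend.errors import GeneMismatch, MissingFrequency, NoOverlap

from conftest import A


def _call(sample, gene, a1, a2):
    zyg = "hom" if a1 == a2 else "het"
    return GenotypeCall(sample, gene, a1, a2, zyg, 0.9, 0.4)


# --- pair concordance --------------------------------------------------------

a, b, c, d = A("A", 1), A("A", 2), A("A", 3), A("A", 4)


@pytest.mark.parametrize(
    "truth,call,expected",
    [
        ((a, b), (b, a), 1.0),   # orientation max
        ((a, a), (a, b), 0.5),
        ((a, b), (c, d), 0.0),
        ((a, b), (a, b), 1.0),
        ((a, a), (b, b), 0.0),
        ((a, b), (a, c), 0.5),
    ],
)
def test_pair_accuracy_cases(truth, call, expected):
    assert pair_accuracy(truth, call) == expected


def test_pair_accuracy_gene_mismatch():
    with pytest.raises(GeneMismatch):
        pair_accuracy((a, b), (A("B", 7, 2), A("B", 7, 2)))


def test_pair_accuracy_swap_symmetric_and_discrete(rng):
    alleles = [A("C", i + 1) for i in range(4)]
    for _ in range(300):
        t = tuple(alleles[i] for i in rng.integers(0, 4, 2))
        y = tuple(alleles[i] for i in rng.integers(0, 4, 2))
        s = pair_accuracy(t, y)
        assert s in (0.0, 0.5, 1.0)
        assert s == pair_accuracy(t[::-1], y) == pair_accuracy(t, y[::-1])
        # oracle: best of the two slot assignments, enumerated directly
        oracle = max(
            int(t[0] == y[0]) + int(t[1] == y[1]),
            int(t[0] == y[1]) + int(t[1] == y[0]),
        ) / 2
        assert s == oracle


# --- cohort accuracy ---------------------------------------------------------

def test_accuracy_mean_of_perfect_and_wrong():
    truth = TruthTable({("s1", "A"): (a, b), ("s2", "A"): (a, b)})
    calls = [_call("s1", "A", a, b), _call("s2", "A", c, d)]
    report = accuracy(truth, calls)
    assert report.overall == pytest.approx(0.5)
    assert report.n_pairs == {"A": 2}


def test_accuracy_identical_calls_are_perfect():
    truth = TruthTable(
        {("s1", "A"): (a, b), ("s1", "B"): (A("B", 7, 2), A("B", 8, 1))}
    )
    calls = [_call("s1", "A", a, b), _call("s1", "B", A("B", 8, 1), A("B", 7, 2))]
    report = accuracy(truth, calls)
    assert report.per_gene == {"A": 1.0, "B": 1.0}
    assert report.overall == 1.0


def test_accuracy_excluded_allele_drops_pair():
    truth = TruthTable({("s1", "A"): (a, b), ("s2", "A"): (c, c)})
    calls = [_call("s1", "A", a, b), _call("s2", "A", c, c)]
    report = accuracy(truth, calls, exclusions={b})
    assert report.n_pairs == {"A": 1}
    assert report.excluded == 1


def test_accuracy_nocalls_are_excluded():
    truth = TruthTable({("s1", "A"): (a, b), ("s2", "A"): (a, b)})
    calls = [_call("s1", "A", a, b), GenotypeCall("s2", "A", None, None, "nocall", 0, 0)]
    report = accuracy(truth, calls)
    assert report.per_gene == {"A": 1.0}
    assert report.excluded == 1


def test_accuracy_group_map_collapses_before_comparison():
    # call differs at two-field level but lands in the truth allele's group
    truth = TruthTable({("s1", "A"): (a, b)})
    calls = [_call("s1", "A", a, c)]
    assert accuracy(truth, calls).overall == 0.5
    gmap = {c: "G1", b: "G1"}
    assert accuracy(truth, calls, group_map=gmap).overall == 1.0


def test_accuracy_requires_overlap():
    truth = TruthTable({("s1", "A"): (a, b)})
    with pytest.raises(NoOverlap):
        accuracy(truth, [_call("s9", "A", a, b)])


def test_single_wrong_allele_costs_half_slot():
    """Replacing one called allele with a novel one lowers a gene's
    accuracy by exactly 1/(2N)."""
    n = 10
    truth = TruthTable({(f"s{i}", "A"): (a, b) for i in range(n)})
    calls = [_call(f"s{i}", "A", a, b) for i in range(n)]
    base = accuracy(truth, calls)
    calls[0] = _call("s0", "A", a, d)  # d never occurs in truth
    dented = accuracy(truth, calls)
    assert base.per_gene["A"] - dented.per_gene["A"] == pytest.approx(1 / (2 * n))


def test_accuracy_oracle_over_random_cohorts(rng):
    """Cohort accuracy equals a direct enumeration of both orientations
    per pair, averaged by hand — 1000 random truth/call draws."""
    alleles = [A("DRB1", i + 1) for i in range(5)]
    for _ in range(100):
        n = int(rng.integers(1, 11))
        truth_pairs = {}
        calls = []
        expected_scores = []
        for i in range(n):
            t = sorted(alleles[j] for j in rng.integers(0, 5, 2))
            y = [alleles[j] for j in rng.integers(0, 5, 2)]
            truth_pairs[(f"s{i}", "DRB1")] = tuple(t)
            calls.append(_call(f"s{i}", "DRB1", y[0], y[1]))
            expected_scores.append(
                max(
                    int(t[0] == y[0]) + int(t[1] == y[1]),
                    int(t[0] == y[1]) + int(t[1] == y[0]),
                ) / 2
            )
        report = accuracy(TruthTable(truth_pairs), calls)
        assert report.per_gene["DRB1"] == pytest.approx(
            sum(expected_scores) / n
        )


def test_error_variance_matches_manual_sample_variance():
    truth = TruthTable(
        {
            ("s1", "A"): (a, b), ("s2", "A"): (a, b),
            ("s1", "B"): (A("B", 7, 2), A("B", 8, 1)),
            ("s2", "B"): (A("B", 7, 2), A("B", 8, 1)),
        }
    )
    calls = [
        _call("s1", "A", a, b), _call("s2", "A", a, b),          # A: acc 1.0
        _call("s1", "B", A("B", 7, 2), A("B", 8, 1)),
        _call("s2", "B", A("B", 9, 9), A("B", 9, 9)),            # B: acc 0.5
    ]
    report = accuracy(truth, calls)
    errors = [0.0, 50.0]
    assert report.error_variance == pytest.approx(np.var(errors, ddof=1))


# --- minor allele frequency --------------------------------------------------

def test_maf_single_set():
    # allele `a` on 3 of 20 chromosomes (10 individuals)
    records = {}
    for i in range(10):
        if i == 0:
            records[(f"s{i}", "A")] = (a, a)        # 2 chromosomes
        elif i == 1:
            records[(f"s{i}", "A")] = (a, b)        # 1 chromosome
        else:
            records[(f"s{i}", "A")] = (b, c)
    maf = compute_maf([TruthTable(records)])
    assert maf[a] == pytest.approx(3 / 20)


def test_maf_excludes_sets_lacking_the_allele():
    set1 = TruthTable(
        {(f"s{i}", "A"): ((a, b) if i < 4 else (b, c)) for i in range(100)}
    )
    set2 = TruthTable({(f"t{i}", "A"): (b, c) for i in range(50)})
    maf = compute_maf([set1, set2])
    # `a` appears 4x in set1 only: denominator excludes set2's 100 chromosomes
    assert maf[a] == pytest.approx(4 / 200)
    # `b` appears in both: pooled over both denominators
    assert maf[b] == pytest.approx((96 + 4 + 50) / (200 + 100))


def test_maf_conserves_chromosome_counts(rng):
    alleles = [A("B", i + 1) for i in range(6)]
    records = {}
    for i in range(50):
        x, y = rng.integers(0, 6, 2)
        records[(f"s{i}", "B")] = tuple(sorted((alleles[x], alleles[y])))
    truth = TruthTable(records)
    maf = compute_maf([truth])
    assert all(0 < f <= 1 for f in maf.values())
    total = sum(maf[al] * 100 for al in maf)  # f * 2N = raw count
    assert total == pytest.approx(100.0)


# --- MAF bins ----------------------------------------------------------------

def test_bin_spec_defaults_partition_half_interval():
    spec = MafBinSpec()
    assert spec.n_bins == 5
    assert spec.bin_index(0.005) == 0
    assert spec.bin_index(0.01) == 1
    assert spec.bin_index(0.07) == 2
    assert spec.bin_index(0.12) == 3
    assert spec.bin_index(0.49) == 4


def test_bin_spec_validation():
    with pytest.raises(ValueError):
        MafBinSpec(edges=(0.05, 0.01))
    with pytest.raises(ValueError):
        MafBinSpec(edges=(0.0, 0.1))
    with pytest.raises(ValueError):
        MafBinSpec(edges=(0.1, 0.6))


def test_minor_frequency_folds_above_half():
    assert minor_frequency(0.7) == pytest.approx(0.3)
    assert minor_frequency(0.2) == pytest.approx(0.2)


def test_binned_accuracy_perfect_calls():
    truth = TruthTable({("s1", "A"): (a, b), ("s2", "A"): (a, a)})
    calls = [_call("s1", "A", a, b), _call("s2", "A", a, a)]
    maf = {a: 0.3, b: 0.007}
    result = binned_accuracy(truth, calls, maf)
    vals = [v for v in result.values() if not math.isnan(v)]
    assert vals and all(v == 1.0 for v in vals)


def test_binned_accuracy_slot_counting():
    # allele `a` (MAF 0.3) occupies 3 truth slots; 2 called correctly
    truth = TruthTable(
        {("s1", "A"): (a, a), ("s2", "A"): (a, b)}
    )
    calls = [_call("s1", "A", a, c), _call("s2", "A", a, b)]
    maf = {a: 0.3, b: 0.3}
    result = binned_accuracy(truth, calls, maf)
    assert result["[0.25,0.5]"] == pytest.approx(3 / 4)  # 4 slots in top bin, 3 correct


def test_binned_accuracy_empty_bin_is_nan_and_totals_match():
    truth = TruthTable({("s1", "A"): (a, b)})
    calls = [_call("s1", "A", a, b)]
    result = binned_accuracy(truth, calls, {a: 0.3, b: 0.3})
    labels = list(result)
    assert math.isnan(result[labels[0]])   # no rare alleles present
    assert result[labels[-1]] == 1.0


def test_binned_accuracy_missing_frequency():
    truth = TruthTable({("s1", "A"): (a, b)})
    with pytest.raises(MissingFrequency):
        binned_accuracy(truth, [_call("s1", "A", a, b)], {a: 0.3})


# --- allelic coverage --------------------------------------------------------

def _panel(pid, alleles):
    return PosteriorTable(pid, frozenset(alleles), {}, ())


def test_coverage_union_and_per_panel():
    p1 = _panel("p1", [A("A", 1), A("A", 2), A("A", 3)])
    p2 = _panel("p2", [A("A", 2), A("A", 3), A("A", 4)])
    report = allele_coverage([p1, p2])
    assert report.union_per_gene == {"A": 4}
    assert report.panel_per_gene["p1"]["A"] == 3
    assert report.panel_per_gene["p2"]["A"] == 3


def test_coverage_single_panel_equals_itself():
    p = _panel("p", [A("B", i + 1) for i in range(5)])
    report = allele_coverage([p])
    assert report.union_per_gene == report.panel_per_gene["p"]


def test_coverage_disjoint_universes_add():
    p1 = _panel("p1", [A("C", i + 1) for i in range(5)])
    p2 = _panel("p2", [A("C", i + 10) for i in range(7)])
    report = allele_coverage([p1, p2])
    assert report.union_per_gene == {"C": 12}
    assert report.union_total == 12
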