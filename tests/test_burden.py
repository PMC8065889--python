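"""Burden statistics and the exact 2x2 test against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from lcmvar.burden import (
    BurdenTable,
    burden_counts,
    class_enrichment_test,
    classify_variants,
    compartment_comparison_test,
    fisher_exact_2x2,
    recurrence_summary,
)
from lcmvar.io_formats import Locus, VariantRecord


def brute_force_two_sided(table):
    """Enumerate every 2x2 table with the observed margins and sum the exact
    rational probabilities of those no more likely than the observed table."""
    (a, b), (c, d) = table
    n1, n2, m1 = a + b, c + d, a + c
    N = a + b + c + d

    def prob(x):
        bb, cc, dd = n1 - x, m1 - x, n2 - (m1 - x)
        if min(x, bb, cc, dd) < 0:
            return None
        return Fraction(
            math.factorial(n1) * math.factorial(n2) * math.factorial(m1) * math.factorial(N - m1),
            math.factorial(N)
            * math.factorial(x)
            * math.factorial(bb)
            * math.factorial(cc)
            * math.factorial(dd),
        )

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(m1 + 1):
        p = prob(x)
        if p is not None and p <= p_obs:
            total += p
    return float(total)


class TestFisherExact:
    def test_cohort_tables_to_printed_precision(self):
        assert round(fisher_exact_2x2([[5, 19], [85, 1211]]), 4) == 0.0199
        assert round(fisher_exact_2x2([[5, 19], [2, 29]]), 4) == 0.2197

    def test_balanced_table_gives_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_extreme_table(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]) < 0.001

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_200_random_tables_match_brute_force_and_scipy(self):
        rng = np.random.default_rng(20210329)
        n_checked = 0
        while n_checked < 200:
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            table = [[a, b], [c, d]]
            p = fisher_exact_2x2(table)
            assert p == pytest.approx(brute_force_two_sided(table), rel=1e-8)
            assert p == pytest.approx(scipy_fisher(table)[1], rel=1e-8)
            n_checked += 1

    def test_invariant_under_transposition_and_swaps(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 20, size=4))
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, rel=1e-10)
            assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, rel=1e-10)
            assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, rel=1e-10)

    def test_one_sided_never_exceeds_neither_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 12, size=4))
            two = fisher_exact_2x2([[a, b], [c, d]])
            less = fisher_exact_2x2([[a, b], [c, d]], alternative="less")
            greater = fisher_exact_2x2([[a, b], [c, d]], alternative="greater")
            assert two <= 1.0
            assert min(less, greater) <= two + 1e-12

    def test_large_counts_do_not_overflow(self):
        # log-space computation: cells far beyond factorial range
        p = fisher_exact_2x2([[5000, 4900], [4950, 5050]])
        assert 0 < p <= 1


def _rec(gene, compartment, patient="P1", pos=None, alt="T"):
    pos = pos if pos is not None else abs(hash((gene, patient))) % 10_000 + 1
    return VariantRecord(
        Locus("chr1", pos, "A", alt), gene=gene, compartment=compartment, patient_id=patient
    )


class TestClassification:
    def test_per_variant_partition(self):
        records = [
            _rec("KRAS", "ECT", pos=1),
            _rec("CSMD3", "ECT", pos=2),
            _rec("CSMD3", "ECT", pos=3),
        ]
        driver, nondriver = classify_variants(records, {"KRAS"})
        assert len(driver) == 1 and len(nondriver) == 2
        assert len(driver) + len(nondriver) == len(records)

    def test_unknown_gene_classifies_nondriver(self):
        records = [_rec("NOT_IN_PANEL", "ECT", pos=5)]
        driver, nondriver = classify_variants(records, {"KRAS"})
        assert driver == [] and len(nondriver) == 1


class TestBurdenCounts:
    def test_cohort_tables(self, cohort_records, panel):
        ect = burden_counts(cohort_records, panel, "ECT")
        assert (ect.n_driver_variants, ect.n_nondriver_variants) == (5, 19)
        assert (ect.n_driver_genes, ect.n_nondriver_genes) == (85, 1211)
        assert round(ect.chance_driver, 3) == 0.059
        assert round(ect.chance_nondriver, 3) == 0.016
        eu = burden_counts(cohort_records, panel, "EU")
        assert (eu.n_driver_variants, eu.n_nondriver_variants) == (2, 29)
        assert round(eu.chance_driver, 3) == 0.024
        assert round(eu.chance_nondriver, 3) == 0.024

    def test_shared_variants_excluded_from_each_compartment(self, cohort_records, panel):
        ect = burden_counts(cohort_records, panel, "ECT")
        eu = burden_counts(cohort_records, panel, "EU")
        n_both = sum(r.compartment == "BOTH" for r in cohort_records)
        assert (
            ect.n_driver_variants
            + ect.n_nondriver_variants
            + eu.n_driver_variants
            + eu.n_nondriver_variants
            + n_both
        ) == len(cohort_records)

    def test_empty_records(self, panel):
        bt = burden_counts([], panel, "ECT")
        assert (bt.n_driver_variants, bt.n_nondriver_variants) == (0, 0)
        assert (bt.n_driver_genes, bt.n_nondriver_genes) == (85, 1211)


class TestEnrichmentTests:
    def test_cohort_p_values(self, cohort_records, panel):
        ect = class_enrichment_test(burden_counts(cohort_records, panel, "ECT"))
        assert round(ect.p_value, 4) == 0.0199
        eu = class_enrichment_test(burden_counts(cohort_records, panel, "EU"))
        assert eu.p_value > 0.05
        p = compartment_comparison_test(ect, eu)
        assert round(p, 4) == 0.2197

    def test_identical_rates_give_p_one(self):
        bt = BurdenTable("ECT", 5, 50, 10, 100)
        assert class_enrichment_test(bt).p_value == pytest.approx(1.0)

    def test_identical_tables_between_compartments(self):
        bt = BurdenTable("ECT", 4, 20, 85, 1211)
        bt2 = BurdenTable("EU", 4, 20, 85, 1211)
        assert compartment_comparison_test(bt, bt2) == pytest.approx(1.0)

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValueError):
            compartment_comparison_test(
                BurdenTable("ECT", 1, 1, 85, 1211), BurdenTable("EU", 1, 1, 80, 1216)
            )


class TestRecurrence:
    def test_cohort_multi_patient_genes(self, cohort_records):
        multi, recurrent = recurrence_summary(cohort_records)
        assert set(multi) == {"ATRX", "RYR1", "DNAH7"}
        assert recurrent == []

    def test_recurrent_variant_detected(self):
        shared_locus = Locus("chr5", 1000, "G", "A")
        records = [
            VariantRecord(shared_locus, gene="X1", compartment="ECT", patient_id="P1"),
            VariantRecord(shared_locus, gene="X1", compartment="EU", patient_id="P2"),
        ]
        multi, recurrent = recurrence_summary(records)
        assert set(multi) == {"X1"}
        assert len(recurrent) == 1

    def test_single_patient_input(self):
        records = [_rec("G1", "ECT", patient="P1", pos=1), _rec("G2", "EU", patient="P1", pos=2)]
        multi, recurrent = recurrence_summary(records)
        assert multi == {} and recurrent == []
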